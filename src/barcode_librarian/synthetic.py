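"""Synthetic barcode reference libraries under a K80 substitution process.

Sequences evolve down a three-level hierarchy (genus ancestor -> species
ancestor -> individual) with fixed per-level branch lengths in expected
substitutions per site, using the exact K80 transition probabilities, so
the expected K2P distance between two specimens equals their genealogical
path length: 2 * depth_individual for conspecifics, 2 * (depth_species +
depth_individual) for congeners, and so on.  Defaults mirror a curated
hoverfly COI library: 26 genera, ~98 species, ~520 barcodes of 658 bp,
pooled intraspecific divergence near 0.007 and congeneric interspecific
divergence near 0.07, with roughly a third of species sampled once.

Pathological structures seen in real libraries can be injected as
scenarios: a ``twin_pair`` of species labels at near-zero divergence, a
``cryptic_split`` where one label covers two divergent clades, a
``shared_haplotype`` copied across two species labels, and a
``singleton_burst`` controlling the fraction of single-specimen species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import dendropy
import numpy as np

from .distances import decode_sequences
from .library_io import ReferenceLibrary, SpecimenRecord

Scenario = Literal["cryptic_split", "twin_pair", "shared_haplotype", "singleton_burst"]

_SUBFAMILIES = ("Eristalinae", "Syrphinae", "Microdontinae")


@dataclass(frozen=True)
class SimulationConfig:
    n_genera: int = 26
    species_per_genus: int = 4
    mean_extra_individuals: float = 5.4   # non-singleton size ~ 2 + Poisson(mean)
    singleton_fraction: float = 32 / 98
    seq_length: int = 658
    kappa: float = 3.0
    depth_genus: float = 0.045
    depth_species: float = 0.0315
    depth_individual: float = 0.0035
    twin_pair_depth: float = 0.0001
    outgroup_depth: float = 0.2
    include_outgroup: bool = True
    scenarios: frozenset[Scenario] = frozenset({"singleton_burst"})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depth_genus", "depth_species", "depth_individual",
                     "twin_pair_depth", "outgroup_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if "twin_pair" in self.scenarios and self.species_per_genus < 2:
            raise ValueError("twin_pair needs at least 2 species per genus")
        if "cryptic_split" in self.scenarios and self.species_per_genus < 2:
            raise ValueError("cryptic_split needs at least 2 species per genus")


@dataclass
class GroundTruth:
    genealogy: dendropy.Tree
    species_of: dict[str, str]
    expected_divergence: dict[str, float]   # pair class -> expected K2P
    scenario_labels: dict[str, list[str]]   # scenario -> affected species labels


def k80_transition_probabilities(branch_length: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after the given branch.

    With transition rate alpha and transversion rate beta (two targets),
    kappa = alpha/beta and branch length d = (alpha + 2 beta) t:

        p_transition      = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
        p_transversion(x) = 1/4 - 1/4 e^{-4 beta t}          (per target x)
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    bt = branch_length / (kappa + 2.0)       # beta * t
    at = kappa * bt                          # alpha * t
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return float(p_same), float(p_ts), float(p_tv)


def evolve(
    seq: np.ndarray | str,
    branch_length: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray | str:
    """Evolve a sequence for the given expected substitutions/site.

    Sites mutate independently with the exact K80 probabilities; encoding
    A=0, G=1, C=2, T=3 makes the transition partner ``base ^ 1`` and the
    transversion targets ``base ^ 2`` and ``base ^ 3``.  Accepts and
    returns either an encoded uint8 array or an A/C/G/T string.
    """
    as_str = isinstance(seq, str)
    if as_str:
        from .distances import encode_sequences

        enc = encode_sequences([seq])[0].copy()
    else:
        enc = np.asarray(seq, dtype=np.uint8).copy()
    if branch_length == 0:
        return decode_sequences(enc[None, :])[0] if as_str else enc
    p_same, p_ts, p_tv = k80_transition_probabilities(branch_length, kappa)
    u = rng.random(enc.shape[0])
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    out = enc.copy()
    out[ts_mask] ^= 1
    out[tv1_mask] ^= 2
    out[tv2_mask] ^= 3
    return decode_sequences(out[None, :])[0] if as_str else out


# encoded (A=0,G=1,C=2,T=3) stop codons of the invertebrate mitochondrial
# code: TAA and TAG
_STOP_CODONS = {(3, 0, 0), (3, 0, 1)}
_SENSE_CODONS = np.array(
    [
        (a, b, c)
        for a in range(4)
        for b in range(4)
        for c in range(4)
        if (a, b, c) not in _STOP_CODONS
    ],
    dtype=np.uint8,
)


def _stop_free_root(seq_length: int, rng: np.random.Generator) -> np.ndarray:
    """Random root sequence with no frame-0 stop codons (coding-like)."""
    n_codons = -(-seq_length // 3)
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return _SENSE_CODONS[idx].reshape(-1)[:seq_length].copy()


def _evolve_coding(
    seq: np.ndarray, branch_length: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve under K80 while keeping frame 0 stop-free (purifying selection).

    Codons that mutate into TAA/TAG are re-evolved from their ancestral
    state until a sense codon results; the conditioning excludes 2 of 64
    codon states and perturbs expected divergence negligibly.
    """
    out = evolve(seq, branch_length, kappa, rng)
    n_full = (len(out) // 3) * 3
    for _ in range(100):
        codons = out[:n_full].reshape(-1, 3)
        bad = np.flatnonzero(
            (codons[:, 0] == 3) & (codons[:, 1] == 0) & (codons[:, 2] <= 1)
        )
        if bad.size == 0:
            return out
        for b in bad:
            anc = seq[3 * b : 3 * b + 3]
            out[3 * b : 3 * b + 3] = evolve(anc, branch_length, kappa, rng)
    raise RuntimeError("failed to draw a stop-free codon")  # pragma: no cover


def _species_sizes(cfg: SimulationConfig, n_species: int, rng: np.random.Generator) -> np.ndarray:
    sizes = 2 + rng.poisson(cfg.mean_extra_individuals, size=n_species)
    if "singleton_burst" in cfg.scenarios and cfg.singleton_fraction > 0:
        n_single = int(round(cfg.singleton_fraction * n_species))
        singles = rng.choice(n_species, size=n_single, replace=False)
        sizes[singles] = 1
    return sizes


def simulate_library(config: SimulationConfig) -> tuple[ReferenceLibrary, GroundTruth]:
    """Simulate a labelled reference library plus its ground truth.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical library.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    root = _stop_free_root(cfg.seq_length, rng)

    taxa = dendropy.TaxonNamespace()
    genealogy = dendropy.Tree(taxon_namespace=taxa)
    genealogy.seed_node.edge.length = 0.0

    records: list[SpecimenRecord] = []
    species_of: dict[str, str] = {}
    scenario_labels: dict[str, list[str]] = {s: [] for s in cfg.scenarios}

    n_species_total = cfg.n_genera * cfg.species_per_genus
    sizes = _species_sizes(cfg, n_species_total, rng)

    # choose scenario targets among multi-specimen species up front
    twin_target: tuple[int, int] | None = None
    cryptic_target: tuple[int, int] | None = None
    shared_target: tuple[int, int] | None = None
    if "twin_pair" in cfg.scenarios:
        twin_target = (0, 1)            # genus 0, species 0 & 1
        sizes[0] = max(sizes[0], 2)
        sizes[1] = max(sizes[1], 2)
    if "cryptic_split" in cfg.scenarios:
        g = 1 % cfg.n_genera
        cryptic_target = (g, 0)         # species 1 of genus g absorbed into species 0
        base = g * cfg.species_per_genus
        sizes[base] = max(sizes[base], 2)
        sizes[base + 1] = max(sizes[base + 1], 2)
    if "shared_haplotype" in cfg.scenarios:
        g = 2 % cfg.n_genera
        shared_target = (g, 0)
        base = g * cfg.species_per_genus
        sizes[base] = max(sizes[base], 2)
        sizes[base + 1] = max(sizes[base + 1], 2)

    sp_index = 0
    for g in range(cfg.n_genera):
        genus_name = f"Genus{g + 1:02d}"
        subfamily = _SUBFAMILIES[g % len(_SUBFAMILIES)]
        genus_anc = _evolve_coding(root, cfg.depth_genus, cfg.kappa, rng)
        genus_node = dendropy.Node()
        genus_node.edge.length = cfg.depth_genus
        genealogy.seed_node.add_child(genus_node)
        species_ancs: list[np.ndarray] = []
        for s in range(cfg.species_per_genus):
            species_name = f"{genus_name} species{s + 1:02d}"
            if twin_target == (g, s) and s == 1:
                # near-zero divergence from the previous species' ancestor
                sp_anc = _evolve_coding(species_ancs[0], cfg.twin_pair_depth, cfg.kappa, rng)
                scenario_labels["twin_pair"] = [
                    f"{genus_name} species01", species_name
                ]
            else:
                sp_anc = _evolve_coding(genus_anc, cfg.depth_species, cfg.kappa, rng)
            species_ancs.append(sp_anc)
            label = species_name
            if cryptic_target == (g, 0) and s == 1:
                # relabel this whole divergent clade with the sibling label
                label = f"{genus_name} species01"
                scenario_labels["cryptic_split"] = [label]
            sp_node = dendropy.Node()
            sp_node.edge.length = (
                cfg.twin_pair_depth if (twin_target == (g, s) and s == 1) else cfg.depth_species
            )
            genus_node.add_child(sp_node)
            for k in range(int(sizes[sp_index])):
                voucher = f"G{g + 1:02d}S{s + 1:02d}I{k + 1:02d}"
                ind = _evolve_coding(sp_anc, cfg.depth_individual, cfg.kappa, rng)
                leaf = dendropy.Node(taxon=taxa.new_taxon(label=voucher))
                leaf.edge.length = cfg.depth_individual
                sp_node.add_child(leaf)
                records.append(
                    SpecimenRecord(
                        voucher_id=voucher,
                        nominal_species=label,
                        genus=genus_name,
                        subfamily=subfamily,
                        sequence=decode_sequences(ind[None, :])[0],
                        source="simulated",
                    )
                )
                species_of[voucher] = label
            sp_index += 1

    if shared_target is not None:
        g, _ = shared_target
        genus_name = f"Genus{g + 1:02d}"
        donors = [r for r in records if r.nominal_species == f"{genus_name} species01"]
        receivers = [r for r in records if r.nominal_species == f"{genus_name} species02"]
        if donors and receivers:
            receivers[0].sequence = donors[0].sequence
            scenario_labels["shared_haplotype"] = [
                donors[0].nominal_species, receivers[0].nominal_species
            ]

    if cfg.include_outgroup:
        og_seq = _evolve_coding(root, cfg.outgroup_depth, cfg.kappa, rng)
        voucher = "OUTG0001"
        leaf = dendropy.Node(taxon=taxa.new_taxon(label=voucher))
        leaf.edge.length = cfg.outgroup_depth
        genealogy.seed_node.add_child(leaf)
        records.append(
            SpecimenRecord(
                voucher_id=voucher,
                nominal_species="Outgroupgenus outgroupspecies",
                genus="Outgroupgenus",
                subfamily="outgroup",
                sequence=decode_sequences(og_seq[None, :])[0],
                source="simulated outgroup",
            )
        )

    if "singleton_burst" in cfg.scenarios:
        counts: dict[str, int] = {}
        for r in records:
            if not r.is_outgroup:
                counts[r.nominal_species] = counts.get(r.nominal_species, 0) + 1
        scenario_labels["singleton_burst"] = sorted(
            sp for sp, c in counts.items() if c == 1
        )

    expected = {
        "intraspecific": 2.0 * cfg.depth_individual,
        "congeneric": 2.0 * (cfg.depth_species + cfg.depth_individual),
        "intergeneric": 2.0 * (cfg.depth_genus + cfg.depth_species + cfg.depth_individual),
    }
    truth = GroundTruth(
        genealogy=genealogy,
        species_of=species_of,
        expected_divergence=expected,
        scenario_labels=scenario_labels,
    )
    return ReferenceLibrary(records), truth
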
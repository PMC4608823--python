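"""Kimura two-parameter distances and their taxonomic partitioning.

The K2P model distinguishes transitions (A<->G, C<->T, proportion P of
compared sites) from transversions (proportion Q) and corrects for multiple
hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Comparisons use pairwise deletion: only sites where both sequences carry an
unambiguous A/C/G/T are counted, so barcodes trimmed to different extents
remain comparable over their shared columns.  When either log argument is
non-positive (saturation) or no sites are comparable, the distance is
flagged undefined and masked, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import HaplotypeTable, ReferenceLibrary

# Encoding: A=0, G=1, C=2, T=3 (transition partners differ only in the low
# bit), anything ambiguous or gapped = 4 and excluded pairwise.
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("AGCT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as an (n, L) uint8 matrix."""
    n = len(seqs)
    if n == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(n, len(seqs[0]))


def decode_sequences(encoded: np.ndarray) -> list[str]:
    lookup = np.frombuffer(b"AGCTN", dtype=np.uint8)
    return [bytes(lookup[row]).decode("ascii") for row in encoded]


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    n_sites: int
    d: float  # nan when undefined
    defined: bool

    def __post_init__(self) -> None:
        assert 0.0 <= self.P <= 1.0 and 0.0 <= self.Q <= 1.0
        assert self.P + self.Q <= 1.0 + 1e-12


def k2p_from_counts(n_transitions: int, n_transversions: int, n_sites: int) -> K2PResult:
    """Evaluate the K2P closed form from site counts."""
    if n_sites == 0:
        return K2PResult(0.0, 0.0, 0, float("nan"), False)
    P = n_transitions / n_sites
    Q = n_transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P, Q, n_sites, float("nan"), False)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P, Q, n_sites, d + 0.0, True)  # +0.0 folds -0.0 away


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal aligned lengths: {len(seq_a)} vs {len(seq_b)}")
    enc = encode_sequences([seq_a, seq_b])
    a, b = enc[0], enc[1]
    both = (a < 4) & (b < 4)
    n = int(both.sum())
    diff = both & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int((diff & ((a >> 1) != (b >> 1))).sum())
    return k2p_from_counts(ts, tv, n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P matrix with an undefined-entry mask."""

    voucher_ids: list[str]
    d: np.ndarray          # (n, n) float, nan on masked entries, 0 diagonal
    P: np.ndarray
    Q: np.ndarray
    n_sites: np.ndarray    # (n, n) int

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.voucher_ids)}

    def __len__(self) -> int:
        return len(self.voucher_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the distance is undefined."""
        return np.isnan(self.d)

    def get(self, voucher_a: str, voucher_b: str) -> float:
        return float(self.d[self._index[voucher_a], self._index[voucher_b]])

    def index_of(self, voucher: str) -> int:
        return self._index[voucher]

    def submatrix(self, voucher_ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[v] for v in voucher_ids])
        return DistanceMatrix(
            list(voucher_ids),
            self.d[np.ix_(idx, idx)],
            self.P[np.ix_(idx, idx)],
            self.Q[np.ix_(idx, idx)],
            self.n_sites[np.ix_(idx, idx)],
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "voucher_a": self.voucher_ids[i],
                        "voucher_b": self.voucher_ids[j],
                        "P": self.P[i, j],
                        "Q": self.Q[i, j],
                        "n_sites": int(self.n_sites[i, j]),
                        "d": self.d[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_phylip(self) -> str:
        """Square PHYLIP serialisation (masked entries rendered as -1)."""
        out = [f"{len(self)}"]
        disp = np.where(np.isnan(self.d), -1.0, self.d)
        for i, v in enumerate(self.voucher_ids):
            vals = " ".join(f"{x:.6f}" for x in disp[i])
            out.append(f"{v:<10s} {vals}")
        return "\n".join(out) + "\n"


def distance_matrix_from_encoded(
    encoded: np.ndarray, voucher_ids: Sequence[str], chunk: int = 64
) -> DistanceMatrix:
    """All-pairs K2P from an encoded alignment, row-chunked to bound memory."""
    n, _ = encoded.shape
    if n < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    valid = encoded < 4
    high = encoded >> 1
    nmat = np.zeros((n, n), dtype=np.int64)
    tsmat = np.zeros((n, n), dtype=np.int64)
    tvmat = np.zeros((n, n), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        v = valid[start:stop, None, :] & valid[None, :, :]
        diff = v & (encoded[start:stop, None, :] != encoded[None, :, :])
        same_class = high[start:stop, None, :] == high[None, :, :]
        nmat[start:stop] = v.sum(axis=2)
        tsmat[start:stop] = (diff & same_class).sum(axis=2)
        tvmat[start:stop] = (diff & ~same_class).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(nmat > 0, tsmat / np.maximum(nmat, 1), 0.0)
        Q = np.where(nmat > 0, tvmat / np.maximum(nmat, 1), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where(
            (w1 > 0) & (w2 > 0) & (nmat > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300)) - 0.25 * np.log(np.maximum(w2, 1e-300)),
            np.nan,
        )
    d = d + 0.0  # fold -0.0 to 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(voucher_ids), d, P, Q, nmat)


def distance_matrix(library: ReferenceLibrary) -> DistanceMatrix:
    """Pairwise K2P matrix over every specimen in the library."""
    if len(library) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    encoded = encode_sequences([r.sequence for r in library])
    return distance_matrix_from_encoded(encoded, library.voucher_ids)


# ---------------------------------------------------------------------------
# Partitioning and summaries


@dataclass
class DistancePartition:
    """Intraspecific vs congeneric-heterospecific distance pools for a group."""

    label: str
    intraspecific: np.ndarray
    congeneric_interspecific: np.ndarray
    n_cross_genus_pairs: int = 0

    @property
    def intra_mean(self) -> float:
        return float(np.mean(self.intraspecific)) if self.intraspecific.size else float("nan")

    @property
    def inter_mean(self) -> float:
        return (
            float(np.mean(self.congeneric_interspecific))
            if self.congeneric_interspecific.size
            else float("nan")
        )


def _pair_class(rec_i, rec_j) -> str:
    if rec_i.nominal_species == rec_j.nominal_species:
        return "intra"
    if rec_i.genus == rec_j.genus:
        return "congeneric"
    return "cross_genus"


def partition(
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    group_by: Literal["dataset", "subfamily", "genus"] = "dataset",
) -> list[DistancePartition]:
    """Pool distances into intraspecific and congeneric-heterospecific sets.

    The outgroup is excluded.  Each unordered specimen pair contributes at
    most once; pairs spanning two genera are counted but pooled in neither
    set.  Undefined (masked) distances are dropped from the pools.
    """
    if group_by not in ("dataset", "subfamily", "genus"):
        raise ValueError(f"unknown group level: {group_by!r}")
    records = [r for r in library if not r.is_outgroup]

    def group_of(rec) -> str:
        if group_by == "dataset":
            return "dataset"
        return rec.subfamily if group_by == "subfamily" else rec.genus

    pools: dict[str, dict[str, list[float]]] = {}
    cross: dict[str, int] = {}
    for rec_i, rec_j in combinations(records, 2):
        gi, gj = group_of(rec_i), group_of(rec_j)
        if gi != gj:
            continue
        pools.setdefault(gi, {"intra": [], "congeneric": []})
        cross.setdefault(gi, 0)
        cls = _pair_class(rec_i, rec_j)
        if cls == "cross_genus":
            cross[gi] += 1
            continue
        dv = matrix.get(rec_i.voucher_id, rec_j.voucher_id)
        if not math.isnan(dv):
            pools[gi][cls].append(dv)
    return [
        DistancePartition(
            label=label,
            intraspecific=np.asarray(p["intra"], dtype=float),
            congeneric_interspecific=np.asarray(p["congeneric"], dtype=float),
            n_cross_genus_pairs=cross[label],
        )
        for label, p in sorted(pools.items())
    ]


@dataclass
class SpeciesSummary:
    species: str
    n_specimens: int
    n_haplotypes: int
    mean_intra: float  # nan for singletons
    max_intra: float
    nn_species: str
    nn_distance: float


def species_summaries(
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    haplotypes: HaplotypeTable | None = None,
) -> list[SpeciesSummary]:
    """Per-species intraspecific statistics and nearest-neighbour species.

    The nearest neighbour is the heterospecific (ingroup) specimen at
    minimum distance from any specimen of the species; singleton species
    get NaN intraspecific fields.
    """
    from .library_io import collapse_haplotypes

    ingroup = library.ingroup()
    if haplotypes is None:
        haplotypes = collapse_haplotypes(ingroup, scope="per-species")
    members = ingroup.species_members()
    vouchers = ingroup.voucher_ids
    idx = {v: matrix.index_of(v) for v in vouchers}
    species_of = {r.voucher_id: r.nominal_species for r in ingroup}

    summaries = []
    for sp, vs in members.items():
        rows = [idx[v] for v in vs]
        if len(vs) >= 2:
            intra = [
                matrix.d[rows[i], rows[j]]
                for i in range(len(rows))
                for j in range(i + 1, len(rows))
            ]
            intra = [x for x in intra if not math.isnan(x)]
            mean_intra = float(np.mean(intra)) if intra else float("nan")
            max_intra = float(np.max(intra)) if intra else float("nan")
        else:
            mean_intra = max_intra = float("nan")
        nn_species, nn_distance = "", float("inf")
        for v_other in vouchers:
            if species_of[v_other] == sp:
                continue
            col = matrix.d[rows, idx[v_other]]
            if np.isnan(col).all():
                continue  # no defined distance to this specimen
            dmin = np.nanmin(col)
            if dmin < nn_distance:
                nn_distance = float(dmin)
                nn_species = species_of[v_other]
        ns, nh = haplotypes.per_species.get(sp, (len(vs), len(vs)))
        summaries.append(
            SpeciesSummary(sp, len(vs), nh, mean_intra, max_intra, nn_species, nn_distance)
        )
    return summaries


def species_summaries_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


@dataclass
class PairSummary:
    species_a: str
    species_b: str
    mean: float
    min: float
    max: float
    n_pairs: int


def pair_summary(
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    species_a: str,
    species_b: str,
) -> PairSummary:
    """Interspecific distance statistics between two nominal species."""
    members = library.species_members()
    for sp in (species_a, species_b):
        if sp not in members:
            raise KeyError(f"species {sp!r} not in library")
    da = [
        matrix.get(va, vb)
        for va in members[species_a]
        for vb in members[species_b]
    ]
    da = [x for x in da if not math.isnan(x)]
    if not da:
        raise ValueError(f"no defined distances between {species_a!r} and {species_b!r}")
    return PairSummary(
        species_a, species_b, float(np.mean(da)), float(np.min(da)), float(np.max(da)), len(da)
    )


def low_divergence_pairs(
    matrix: DistanceMatrix,
    library: ReferenceLibrary,
    cutoff: float = 0.03,
    congeneric_only: bool = True,
) -> list[PairSummary]:
    """All species pairs whose mean interspecific distance is below cutoff."""
    ingroup = library.ingroup()
    genus_of = {r.nominal_species: r.genus for r in ingroup}
    species = list(ingroup.species_members())
    out = []
    for sa, sb in combinations(species, 2):
        if congeneric_only and genus_of[sa] != genus_of[sb]:
            continue
        ps = pair_summary(matrix, ingroup, sa, sb)
        if ps.mean < cutoff:
            out.append(ps)
    return out


def specimens_vs_haplotypes_correlation(
    table: HaplotypeTable, exclude_singletons: bool = True
) -> tuple[float, float, int]:
    """Spearman rank correlation between per-species specimen and haplotype counts.

    Returns ``(R_s, t, n)`` with the t-statistic from
    ``t = R_s * sqrt((n - 2) / (1 - R_s**2))``; ties receive average ranks.
    """
    pairs = [
        (ns, nh)
        for ns, nh in table.per_species.values()
        if not (exclude_singletons and ns == 1)
    ]
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 species for a rank correlation")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rs = float(stats.spearmanr(x, y).statistic)
    if abs(rs) >= 1.0:
        t = math.inf if rs > 0 else -math.inf
    else:
        t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    return rs, float(t), n
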
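"""Reading, writing and curating aligned barcode reference libraries.

A reference library couples a gap-padded multiple alignment of COI barcodes
(one record per vouchered specimen) with a specimen metadata table carrying
the nominal-species label, genus and subfamily of every voucher.  Nominal
species labels are opaque strings: provisional designations such as
``"Genus cf. epithet"``, ``"Genus sp. 1"`` or slash-joined alternatives are
kept verbatim and treated as distinct identification units.

The module also applies the standard barcode quality filters (minimum
ungapped length, absence of internal stop codons under the invertebrate
mitochondrial code) and collapses identical sequences into haplotypes.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
GAP_CHARS = frozenset("-?")
#: NCBI translation table for the invertebrate mitochondrial code.
INVERTEBRATE_MITO_TABLE = 5

OUTGROUP_SUBFAMILY = "outgroup"


class LibraryError(ValueError):
    """Malformed library input (duplicate vouchers, unmatched metadata, ...)."""


@dataclass(frozen=True)
class LabelConfig:
    """Column naming for the metadata table.

    Defaults match the required schema: ``voucher_id``, ``species``,
    ``genus``, ``subfamily``; a free-text ``source`` column is optional.
    """

    voucher_col: str = "voucher_id"
    species_col: str = "species"
    genus_col: str = "genus"
    subfamily_col: str = "subfamily"
    source_col: str = "source"


@dataclass
class SpecimenRecord:
    """One barcode sequence with its voucher and taxonomy labels."""

    voucher_id: str
    nominal_species: str
    genus: str
    subfamily: str
    sequence: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.voucher_id:
            raise LibraryError("voucher_id must be nonempty")
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_CODES - GAP_CHARS
        if bad:
            raise LibraryError(
                f"{self.voucher_id}: non-IUPAC characters in sequence: {sorted(bad)}"
            )
        self.sequence = seq
        if self.genus and not self.nominal_species.startswith(self.genus.split()[0]):
            raise LibraryError(
                f"{self.voucher_id}: nominal species {self.nominal_species!r} "
                f"does not begin with genus {self.genus!r}"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.sequence)

    @property
    def ungapped_sequence(self) -> str:
        return "".join(c for c in self.sequence if c not in GAP_CHARS)

    @property
    def is_outgroup(self) -> bool:
        return self.subfamily.lower() == OUTGROUP_SUBFAMILY


@dataclass
class ReferenceLibrary:
    """An ordered, aligned collection of specimen records."""

    records: list[SpecimenRecord]
    alignment_width: int = 0

    def __post_init__(self) -> None:
        if self.records:
            widths = {r.aligned_length for r in self.records}
            if len(widths) > 1:
                raise LibraryError(f"ragged alignment: widths {sorted(widths)}")
            width = widths.pop()
            if self.alignment_width and self.alignment_width != width:
                raise LibraryError("alignment_width does not match records")
            self.alignment_width = width
        seen = Counter(r.voucher_id for r in self.records)
        dups = [v for v, k in seen.items() if k > 1]
        if dups:
            raise LibraryError(f"duplicate voucher ids: {dups}")
        self._by_voucher = {r.voucher_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __getitem__(self, voucher_id: str) -> SpecimenRecord:
        return self._by_voucher[voucher_id]

    def __contains__(self, voucher_id: str) -> bool:
        return voucher_id in self._by_voucher

    @property
    def voucher_ids(self) -> list[str]:
        return [r.voucher_id for r in self.records]

    def ingroup(self) -> "ReferenceLibrary":
        """The library without outgroup records."""
        return ReferenceLibrary([r for r in self.records if not r.is_outgroup])

    def subset(self, voucher_ids: Iterable[str]) -> "ReferenceLibrary":
        keep = set(voucher_ids)
        return ReferenceLibrary([r for r in self.records if r.voucher_id in keep])

    def species_members(self) -> dict[str, list[str]]:
        """Nominal species -> vouchers, in library order (outgroup included)."""
        out: dict[str, list[str]] = defaultdict(list)
        for r in self.records:
            out[r.nominal_species].append(r.voucher_id)
        return dict(out)

    def singleton_species(self) -> set[str]:
        return {sp for sp, vs in self.ingroup().species_members().items() if len(vs) == 1}


@dataclass(frozen=True)
class QCReport:
    voucher_id: str
    passed: bool
    ungapped_length: int
    frame: int
    n_stop_codons: int
    reason: str = ""


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    member_vouchers: list[str]
    nominal_species: frozenset[str]


@dataclass
class HaplotypeTable:
    """Result of collapsing identical sequences.

    ``per_species`` maps each nominal species to ``(n_specimens,
    n_haplotypes)``; under global scope a haplotype shared across species
    is counted once for each species it occurs in.
    """

    haplotypes: list[Haplotype]
    scope: Literal["per-species", "global"]
    per_species: dict[str, tuple[int, int]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_specimens(self) -> int:
        return sum(len(h.member_vouchers) for h in self.haplotypes)

    def mean_haplotypes_per_species(self, exclude_singletons: bool = True) -> float:
        counts = [
            nh for sp, (ns, nh) in self.per_species.items()
            if not (exclude_singletons and ns == 1)
        ]
        if not counts:
            raise ValueError("no species left after singleton exclusion")
        return sum(counts) / len(counts)

    def representatives(self) -> list[str]:
        """One voucher per haplotype (the first member, library order)."""
        return [h.member_vouchers[0] for h in self.haplotypes]


# ---------------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path: str | Path, config: LabelConfig) -> pd.DataFrame:
    """Read the metadata table; TSV vs CSV is decided from the header line."""
    path = Path(metadata_path)
    header = path.read_text().splitlines()[0] if path.stat().st_size else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [
        c for c in (config.voucher_col, config.species_col,
                    config.genus_col, config.subfamily_col)
        if c not in df.columns
    ]
    if missing:
        raise LibraryError(f"metadata is missing required columns: {missing}")
    dups = df[config.voucher_col][df[config.voucher_col].duplicated()].tolist()
    if dups:
        raise LibraryError(f"duplicate voucher ids in metadata: {dups}")
    return df


def read_library(
    fasta_path: str | Path,
    metadata_path: str | Path,
    config: LabelConfig = LabelConfig(),
) -> ReferenceLibrary:
    """Read an aligned multi-FASTA plus metadata table into a library.

    FASTA ids (first whitespace-delimited token of the header) must resolve
    to metadata rows by voucher id; every FASTA entry becomes one record.
    """
    meta = _read_metadata(metadata_path, config).set_index(config.voucher_col)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        voucher = rec.id
        if voucher not in meta.index:
            raise LibraryError(f"FASTA voucher {voucher!r} has no metadata row")
        row = meta.loc[voucher]
        records.append(
            SpecimenRecord(
                voucher_id=voucher,
                nominal_species=row[config.species_col],
                genus=row[config.genus_col],
                subfamily=row[config.subfamily_col],
                sequence=str(rec.seq),
                source=row.get(config.source_col, "") or None,
            )
        )
    return ReferenceLibrary(records)


def write_library(
    library: ReferenceLibrary,
    fasta_path: str | Path,
    metadata_path: str | Path,
    config: LabelConfig = LabelConfig(),
) -> None:
    """Write the library back out (FASTA + TSV); round-trips byte-exactly."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.voucher_id, description="")
        for r in library
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")
    rows = [
        {
            config.voucher_col: r.voucher_id,
            config.species_col: r.nominal_species,
            config.genus_col: r.genus,
            config.subfamily_col: r.subfamily,
            config.source_col: r.source or "",
        }
        for r in library
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


def _count_stops(ungapped: str, frame: int) -> int:
    sub = ungapped[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return 0
    aa = str(Seq(sub).translate(table=INVERTEBRATE_MITO_TABLE))
    return aa.count("*")


def qc_report(
    record: SpecimenRecord,
    min_length: int = 550,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> QCReport:
    """QC one record: ungapped length and stop codons in the best frame.

    The reading frame is the one among {0, 1, 2} minimising the number of
    stop codons, ties resolved toward frame 0; a record passes iff its
    ungapped length strictly exceeds ``min_length`` and the chosen frame is
    stop-free.
    """
    ungapped = record.ungapped_sequence
    stops = [_count_stops(ungapped, f) for f in range(3)]
    frame = int(min(range(3), key=lambda f: stops[f]))
    n_stop = stops[frame]
    reasons = []
    if len(ungapped) <= min_length:
        reasons.append(f"length <= {min_length}")
    if n_stop > 0:
        reasons.append(f"{n_stop} stop codon(s) in frame {frame}")
    return QCReport(
        voucher_id=record.voucher_id,
        passed=not reasons,
        ungapped_length=len(ungapped),
        frame=frame,
        n_stop_codons=n_stop,
        reason="; ".join(reasons),
    )


def qc_filter(
    library: ReferenceLibrary,
    min_length: int = 550,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> tuple[ReferenceLibrary, list[QCReport]]:
    """Split a library into passing records and a full QC report list."""
    if not len(library):
        raise LibraryError("empty library")
    reports = [qc_report(r, min_length, genetic_code) for r in library]
    passed = {rep.voucher_id for rep in reports if rep.passed}
    return library.subset(passed), reports


def qc_reports_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


# ---------------------------------------------------------------------------
# Haplotype collapsing


def collapse_haplotypes(
    library: ReferenceLibrary,
    scope: Literal["per-species", "global"] = "per-species",
) -> HaplotypeTable:
    """Group identical aligned sequences into haplotypes.

    Identity is exact string equality over the full alignment width, so
    sequences trimmed to different extents are distinct haplotypes even if
    they agree on every shared column.  ``per-species`` scope additionally
    keys on the nominal species, so an identical sequence occurring in two
    species yields two haplotypes.
    """
    groups: dict[tuple, list[SpecimenRecord]] = defaultdict(list)
    for r in library:
        key = (r.nominal_species, r.sequence) if scope == "per-species" else (r.sequence,)
        groups[key].append(r)
    haplotypes = [
        Haplotype(
            haplotype_id=f"H{i + 1:04d}",
            sequence=members[0].sequence,
            member_vouchers=[m.voucher_id for m in members],
            nominal_species=frozenset(m.nominal_species for m in members),
        )
        for i, members in enumerate(groups.values())
    ]
    n_spec: Counter[str] = Counter()
    n_hap: Counter[str] = Counter()
    for r in library:
        n_spec[r.nominal_species] += 1
    for h in haplotypes:
        for sp in h.nominal_species:
            n_hap[sp] += 1
    per_species = {sp: (n_spec[sp], n_hap[sp]) for sp in n_spec}
    return HaplotypeTable(haplotypes=haplotypes, scope=scope, per_species=per_species)
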
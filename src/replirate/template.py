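"""Assay-template toolkit: motif search, amplicon mapping, cassette calling.

The helicase assay measures unwinding as protection from MseI digestion, so
its design hinges on where the TTAA motifs sit relative to the qPCR
amplicons. This module parses the template sequence, finds motif occurrences
(overlaps included), locates the primer-delimited amplicons and verifies that
every non-control amplicon covers a tandem cassette of motifs while the
control amplicon covers none.

Coordinates are 0-based, half-open, on the plus strand; the template is
treated as linear (the assay template is ScaI-linearised), so there are no
wraparound matches. Primer matching is exact: the assay was designed against
an exactly known synthetic sequence.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ValidationError

_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MSEI_MOTIF = "TTAA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Template:
    """A linear plus-strand DNA template."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"template {self.id!r}: empty sequence")
        bad = next(
            (i for i, c in enumerate(self.sequence) if c not in _ALPHABET), None
        )
        if bad is not None:
            raise ValidationError(
                f"template {self.id!r}: non-ACGT character "
                f"{self.sequence[bad]!r} at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One plus-strand occurrence of a motif."""

    offset: int
    motif: str


@dataclass(frozen=True)
class PrimerPair:
    """A qPCR primer pair; the reverse primer is given 5'->3' on the minus strand."""

    name: str
    site_label: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for role, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValidationError(
                    f"primer pair {self.name!r}: {role} primer shorter than 10 nt"
                )
            if not set(p) <= _ALPHABET:
                raise ValidationError(
                    f"primer pair {self.name!r}: {role} primer has non-ACGT characters"
                )


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited qPCR product on the template, with its motif content."""

    pair_name: str
    site_label: str
    start: int
    end: int
    motif_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_control(self) -> bool:
        return self.motif_count == 0


@dataclass(frozen=True)
class Cassette:
    """A tandem cluster of motif hits."""

    hits: tuple[MotifHit, ...]
    motif_length: int

    @property
    def n_sites(self) -> int:
        return len(self.hits)

    @property
    def span(self) -> int:
        return self.hits[-1].offset + self.motif_length - self.hits[0].offset


@dataclass
class AssayMap:
    """Amplicons keyed by site label, with design-check warnings."""

    amplicons: dict[str, Amplicon]
    warnings: list[str] = field(default_factory=list)

    @property
    def control_label(self) -> str:
        return next(l for l, a in self.amplicons.items() if a.is_control)


def read_fasta(path: str | Path, record: int = 0) -> Template:
    """Read one record from a FASTA file as a Template.

    Lowercase input is upcased; gap characters and whitespace are stripped.
    A non-ACGT character after cleanup is rejected with its position named.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    if not 0 <= record < len(records):
        raise ValidationError(
            f"record index {record} out of range ({len(records)} records in {path})"
        )
    rec = records[record]
    seq = str(rec.seq).upper().replace("-", "").replace(" ", "")
    if not seq:
        raise ValidationError(f"FASTA record {rec.id!r} in {path} is empty")
    return Template(id=rec.id, sequence=seq)


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read a primer-table TSV (site_label, primer_name_fwd, primer_name_rev,
    seq_fwd, seq_rev)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"primer table not found: {path}")
    required = {"site_label", "primer_name_fwd", "primer_name_rev", "seq_fwd", "seq_rev"}
    pairs: list[PrimerPair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValidationError(f"primer table {path}: missing columns {missing}")
        for row in reader:
            pairs.append(
                PrimerPair(
                    name=f"{row['primer_name_fwd']}/{row['primer_name_rev']}",
                    site_label=row["site_label"],
                    forward=row["seq_fwd"].upper(),
                    reverse=row["seq_rev"].upper(),
                )
            )
    if not pairs:
        raise ValidationError(f"primer table {path} has no rows")
    return pairs


def find_motif_sites(template: Template, motif: str = MSEI_MOTIF) -> list[MotifHit]:
    """All plus-strand occurrences of ``motif``, overlapping ones included,
    in ascending offset order."""
    if not motif:
        raise ValidationError("empty motif")
    motif = motif.upper()
    if len(motif) > template.length:
        raise ValidationError("motif longer than template")
    hits: list[MotifHit] = []
    start = template.sequence.find(motif)
    while start != -1:
        hits.append(MotifHit(offset=start, motif=motif))
        start = template.sequence.find(motif, start + 1)
    return hits


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_amplicon(
    template: Template, pair: PrimerPair, motif: str = MSEI_MOTIF
) -> Amplicon:
    """Locate the qPCR product of ``pair`` on the template.

    The forward primer must match the plus strand exactly once; the reverse
    primer's reverse complement must match the plus strand exactly once,
    downstream of the forward match. The amplicon runs from the first base of
    the forward primer through the last base complementary to the reverse
    primer (half-open end). Motifs are counted only when they lie fully
    inside the amplicon.
    """
    fwd_occ = _occurrences(template.sequence, pair.forward)
    if not fwd_occ:
        raise ValidationError(f"primer not found: forward primer of {pair.name}")
    if len(fwd_occ) > 1:
        raise ValidationError(
            f"ambiguous primer: forward primer of {pair.name} matches "
            f"{len(fwd_occ)} times"
        )
    rev_rc = reverse_complement(pair.reverse)
    rev_occ = _occurrences(template.sequence, rev_rc)
    if not rev_occ:
        raise ValidationError(f"primer not found: reverse primer of {pair.name}")
    if len(rev_occ) > 1:
        raise ValidationError(
            f"ambiguous primer: reverse primer of {pair.name} matches "
            f"{len(rev_occ)} times"
        )
    start = fwd_occ[0]
    end = rev_occ[0] + len(pair.reverse)
    if rev_occ[0] < start + len(pair.forward):
        raise ValidationError(
            f"reverse primer of {pair.name} binds upstream of the forward primer"
        )
    n_motifs = sum(
        1
        for h in find_motif_sites(template, motif)
        if h.offset >= start and h.offset + len(motif) <= end
    )
    return Amplicon(
        pair_name=pair.name,
        site_label=pair.site_label,
        start=start,
        end=end,
        motif_count=n_motifs,
    )


def find_cassettes(
    template: Template,
    motif: str = MSEI_MOTIF,
    min_sites: int = 4,
    max_span: int = 30,
) -> list[Cassette]:
    """Find tandem clusters of motif hits.

    Hits are grouped greedily: consecutive hits belong to the same cluster
    when their offsets differ by at most ``max_span / min_sites``. Clusters
    with at least ``min_sites`` hits and total span (first hit start to last
    hit end) at most ``max_span`` are returned, non-overlapping and in
    ascending order.
    """
    if min_sites < 2:
        raise ValidationError("min_sites must be >= 2")
    if max_span < min_sites * len(motif):
        raise ValidationError("max_span must be >= min_sites * motif length")
    hits = find_motif_sites(template, motif)
    gap = max_span / min_sites
    clusters: list[list[MotifHit]] = []
    for h in hits:
        if clusters and h.offset - clusters[-1][-1].offset <= gap:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    out = []
    for cl in clusters:
        cas = Cassette(hits=tuple(cl), motif_length=len(motif))
        if cas.n_sites >= min_sites and cas.span <= max_span:
            out.append(cas)
    return out


def map_assay(
    template: Template,
    primer_table: Sequence[PrimerPair],
    motif: str = MSEI_MOTIF,
) -> AssayMap:
    """Map every primer pair to its amplicon and check the assay design.

    Exactly one amplicon must be motif-free (the loading control); the
    motif-bearing amplicons are expected to share a common motif count, and a
    warning is recorded if they do not.
    """
    if not primer_table:
        raise ValidationError("primer table is empty")
    labels = [p.site_label for p in primer_table]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise ValidationError(f"duplicated site labels: {sorted(dup)}")
    amplicons = {p.site_label: locate_amplicon(template, p, motif) for p in primer_table}
    controls = [l for l, a in amplicons.items() if a.is_control]
    if len(controls) == len(amplicons):
        raise ValidationError("no motif-bearing amplicon in the primer table")
    if not controls:
        raise ValidationError("no motif-free control amplicon in the primer table")
    if len(controls) > 1:
        raise ValidationError(
            f"multiple motif-free (control) amplicons: {sorted(controls)}"
        )
    warnings = []
    counts = {a.motif_count for a in amplicons.values() if not a.is_control}
    if len(counts) > 1:
        warnings.append(
            f"non-control amplicons have unequal motif counts: {sorted(counts)}"
        )
    return AssayMap(amplicons=amplicons, warnings=warnings)


def write_assay_map_tsv(assay_map: AssayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_label\tstart\tend\tlength\tmotif_count\tis_control\n")
        for label, a in assay_map.amplicons.items():
            fh.write(
                f"{label}\t{a.start}\t{a.end}\t{a.length}\t{a.motif_count}"
                f"\t{str(a.is_control).lower()}\n"
            )


def write_assay_map_json(assay_map: AssayMap, path: str | Path) -> None:
    payload = {
        "amplicons": {
            label: {
                "pair_name": a.pair_name,
                "start": a.start,
                "end": a.end,
                "length": a.length,
                "motif_count": a.motif_count,
                "is_control": a.is_control,
            }
            for label, a in assay_map.amplicons.items()
        },
        "warnings": assay_map.warnings,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
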
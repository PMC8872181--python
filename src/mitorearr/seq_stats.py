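"""Composition, skew, codon-usage/RSCU, start/stop and distance statistics.

Conventions
-----------
* AT-skew = (A - T) / (A + T), GC-skew = (G - C) / (G + C), computed on
  counts (equivalently percentages); both lie in [-1, 1] and are undefined
  (``None``) when the denominator is zero.
* ``N`` bases and alignment gaps never enter a denominator.
* Codon statistics use the vertebrate mitochondrial genetic code
  (translation table 2): AGA/AGG are termination codons, ATA is Met,
  TGA is Trp.  Complete terminal stop codons and trailing incomplete
  codons (``T--`` / ``TA-``, completed by polyadenylation in vivo) are
  tabulated separately and excluded from amino-acid totals.
* RSCU (relative synonymous codon usage) for codon c in synonymous family
  F: ``count(c) * |F| / sum(count(F))``; an evenly used family has RSCU 1
  for every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .mito_io import GeneFeature, MitogenomeRecord

__all__ = [
    "BaseComposition",
    "RegionStats",
    "CodonUsageTable",
    "StartStopTable",
    "SpacerOverlapReport",
    "base_composition",
    "region_stats",
    "codon_usage",
    "start_stop_table",
    "spacers_and_overlaps",
    "p_distance",
    "VERTEBRATE_MITO_STOPS",
]

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
VERTEBRATE_MITO_STOPS = tuple(sorted(_MITO_TABLE.stop_codons))  # AGA AGG TAA TAG

#: synonymous families under table 2, keyed by amino acid letter
_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _MITO_TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, ())
    _FAMILIES[_aa] = _FAMILIES[_aa] + (_codon,)

#: display label distinguishing the isoacceptor groups the field reports
#: (Leu1 = CUN, Leu2 = UUR, Ser1 = AGY, Ser2 = UCN)
def _codon_display_aa(codon: str, aa: str) -> str:
    if aa == "L":
        return "Leu1" if codon.startswith("CT") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    three = {
        "F": "Phe", "I": "Ile", "M": "Met", "V": "Val", "P": "Pro",
        "T": "Thr", "A": "Ala", "Y": "Tyr", "H": "His", "Q": "Gln",
        "N": "Asn", "K": "Lys", "D": "Asp", "E": "Glu", "C": "Cys",
        "W": "Trp", "R": "Arg", "G": "Gly",
    }
    return three[aa]


@dataclass(frozen=True)
class BaseComposition:
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> Optional[float]:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)

    def as_row(self) -> dict:
        """Report row: percentages to 1 decimal, skews to 3 decimals."""
        def r3(x):
            return None if x is None else round(x, 3)
        return {
            "length": self.total,
            "T%": round(100.0 * self.t / self.total, 1),
            "C%": round(100.0 * self.c / self.total, 1),
            "A%": round(100.0 * self.a / self.total, 1),
            "G%": round(100.0 * self.g / self.total, 1),
            "AT%": round(self.at_content, 1),
            "GC%": round(self.gc_content, 1),
            "AT-skew": r3(self.at_skew),
            "GC-skew": r3(self.gc_skew),
        }


def base_composition(seq: str) -> BaseComposition:
    """Count A/C/G/T (N excluded) and derive contents and skews."""
    s = seq.upper()
    comp = BaseComposition(a=s.count("A"), c=s.count("C"),
                           g=s.count("G"), t=s.count("T"))
    if comp.total == 0:
        raise ValueError("sequence empty after removing N bases")
    return comp


@dataclass(frozen=True)
class RegionStats:
    region: str  # whole | PCG | tRNA | rRNA | CR
    composition: BaseComposition
    total_length: int


def region_stats(record: MitogenomeRecord) -> list[RegionStats]:
    """Per-class composition: whole genome (H-strand) plus each feature class
    (feature-strand sequence, features concatenated in genome order)."""
    rows = [RegionStats("whole", base_composition(record.sequence), record.length)]
    for cls in ("PCG", "tRNA", "rRNA", "CR"):
        feats = record.features_of_class(cls)
        if not feats:
            continue
        concat = "".join(record.feature_sequence(f) for f in feats)
        rows.append(RegionStats(cls, base_composition(concat), len(concat)))
    return rows


def composition_table(stats: Sequence[RegionStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {"region": s.region}
        row.update(s.composition.as_row())
        row["length"] = s.total_length
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CodonUsageTable:
    """Codon counts, amino-acid family totals and RSCU for a record's PCGs."""

    codon_counts: dict[str, int]
    aa_totals: dict[str, int]
    rscu: dict[str, Optional[float]]
    stop_counts: dict[str, int] = field(default_factory=dict)
    incomplete_stops: int = 0
    skipped_genes: list[str] = field(default_factory=list)

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aa, codons in sorted(_FAMILIES.items()):
            for codon in sorted(codons):
                rows.append({
                    "codon": codon.replace("T", "U"),
                    "amino_acid": _codon_display_aa(codon, aa),
                    "count": self.codon_counts.get(codon, 0),
                    "rscu": self.rscu.get(codon),
                })
        return pd.DataFrame(rows)


def _coding_frames(record: MitogenomeRecord):
    """Yield (gene label, coding-strand sequence) for each PCG, in genome
    order; genes shorter than 6 bp are yielded with ``None`` sequence."""
    for f in record.features_of_class("PCG"):
        seq = record.feature_sequence(f)
        yield f.name.canonical_label, (seq if len(seq) >= 6 else None)


def codon_usage(record: MitogenomeRecord) -> CodonUsageTable:
    """Tabulate codon usage and RSCU over every annotated protein gene.

    Each gene is read in frame from its first (start) codon.  The final
    complete triplet, if it is a termination codon, and any trailing
    incomplete codon are excluded from the amino-acid totals.
    """
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    incomplete = 0
    skipped: list[str] = []
    for label, seq in _coding_frames(record):
        if seq is None:
            skipped.append(label)
            continue
        n_full = len(seq) // 3
        trailing = len(seq) - 3 * n_full
        codons = [seq[3 * i:3 * i + 3] for i in range(n_full)]
        if trailing:
            incomplete += 1
        elif codons and codons[-1] in VERTEBRATE_MITO_STOPS:
            stops[codons[-1]] = stops.get(codons[-1], 0) + 1
            codons = codons[:-1]
        for c in codons:
            if "N" in c:
                continue
            counts[c] = counts.get(c, 0) + 1

    aa_totals: dict[str, int] = {}
    rscu: dict[str, Optional[float]] = {}
    for aa, codons in _FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        aa_totals[aa] = total
        for c in codons:
            rscu[c] = (counts.get(c, 0) * len(codons) / total) if total else None
    return CodonUsageTable(
        codon_counts=counts, aa_totals=aa_totals, rscu=rscu,
        stop_counts=stops, incomplete_stops=incomplete, skipped_genes=skipped,
    )


@dataclass(frozen=True)
class StartStopEntry:
    gene: str
    start_codon: str
    stop_codon: str  # e.g. "TAA", "AGA", "T--", "TA-"
    complete: bool


@dataclass
class StartStopTable:
    entries: list[StartStopEntry]

    def by_gene(self) -> dict[str, StartStopEntry]:
        return {e.gene: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def start_stop_table(record: MitogenomeRecord) -> StartStopTable:
    """Initiation and termination codon of every protein gene.

    Stop classification: a gene whose length is a multiple of three ends in a
    complete codon; otherwise the 1-2 trailing bases form an incomplete stop
    reported as ``T--`` / ``TA-``.
    """
    entries = []
    for label, seq in _coding_frames(record):
        if seq is None:
            continue
        start = seq[:3]
        r = len(seq) % 3
        if r == 0:
            stop, complete = seq[-3:], True
        else:
            stop, complete = seq[3 * (len(seq) // 3):] + "-" * (3 - r), False
        entries.append(StartStopEntry(label, start, stop, complete))
    return StartStopTable(entries)


@dataclass(frozen=True)
class AdjacentPair:
    upstream: GeneFeature
    downstream: GeneFeature
    gap: int  # negative = overlap, 0 = abutting, positive = spacer


@dataclass
class SpacerOverlapReport:
    pairs: list[AdjacentPair]

    @property
    def n_overlaps(self) -> int:
        return sum(1 for p in self.pairs if p.gap < 0)

    @property
    def n_spacers(self) -> int:
        return sum(1 for p in self.pairs if p.gap > 0)

    @property
    def max_overlap(self) -> int:
        return max((-p.gap for p in self.pairs if p.gap < 0), default=0)

    @property
    def max_spacer(self) -> int:
        return max((p.gap for p in self.pairs if p.gap > 0), default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "upstream": p.upstream.name.canonical_label,
                "downstream": p.downstream.name.canonical_label,
                "gap": p.gap,
                "kind": "overlap" if p.gap < 0 else
                        ("spacer" if p.gap > 0 else "abutting"),
            }
            for p in self.pairs
        ])


def spacers_and_overlaps(record: MitogenomeRecord) -> SpacerOverlapReport:
    """Signed gap between every circularly adjacent feature pair.

    The closing pair (last feature back to the first) is included, so the
    number of pairs equals the number of features.
    """
    feats = record.features
    if len(feats) < 2:
        raise ValueError("need at least two features for adjacency analysis")
    pairs = []
    for prev, nxt in zip(feats, feats[1:]):
        pairs.append(AdjacentPair(prev, nxt, nxt.start - prev.end))
    last, first = feats[-1], feats[0]
    pairs.append(AdjacentPair(last, first, first.start + record.length - last.end))
    return SpacerOverlapReport(pairs)


_GAPLIKE = set("-.Nn")


def p_distance(aligned_a: str, aligned_b: str) -> Optional[float]:
    """Uncorrected p-distance between two aligned sequences.

    The proportion of differing columns among columns where both sequences
    carry a non-gap, non-N base; ``None`` when no column is comparable.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        return None
    return diffs / comparable


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
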
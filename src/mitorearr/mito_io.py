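"""Reading, writing and in-memory representation of annotated mitogenomes.

The central container is :class:`MitogenomeRecord`: a circular DNA sequence
plus an ordered list of :class:`GeneFeature` annotations whose names come
from a closed controlled vocabulary (13 protein-coding genes, 22 tRNAs with
the Leu1/Leu2 and Ser1/Ser2 isoacceptor split, the two rRNAs, the control
region and the light-strand replication origin).

Coordinates are 0-based half-open on the forward (heavy) strand.  A feature
that spans the origin of the circular molecule is stored *unwrapped*, with
``end`` exceeding the sequence length and interpreted modulo the length, so
ordinary ``end - start`` arithmetic gives its true span.  GenBank flat files
(1-based inclusive, ``join()`` locations across the origin) are converted on
the way in and out by :func:`read_genbank` / :func:`write_genbank`.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG_LABELS",
    "TRNA_LABELS",
    "RRNA_LABELS",
    "VOCABULARY",
    "GeneName",
    "GeneFeature",
    "MitogenomeRecord",
    "GeneNameError",
    "GenBankFormatError",
    "EmptyInputError",
    "normalize_gene_name",
    "feature_class_of",
    "feature_length",
    "assign_copy_labels",
    "read_genbank",
    "write_genbank",
    "write_skipped_log",
    "write_feature_fasta",
    "apply_annotation_patch",
]


class GeneNameError(KeyError):
    """Raised for a feature name outside the controlled vocabulary."""


class GenBankFormatError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no records."""


# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

PCG_LABELS = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

#: three-letter amino-acid codes; Leu1 = CUN codons, Leu2 = UUR,
#: Ser1 = AGY, Ser2 = UCN (the conventional mitochondrial isoacceptor split)
_TRNA_AA = (
    "Phe", "Val", "Leu1", "Leu2", "Ile", "Gln", "Met", "Trp", "Ala", "Asn",
    "Cys", "Tyr", "Ser1", "Ser2", "Asp", "Lys", "Gly", "Arg", "His", "Glu",
    "Thr", "Pro",
)
TRNA_LABELS = tuple(f"tRNA-{aa}" for aa in _TRNA_AA)

RRNA_LABELS = ("rrnS", "rrnL")

VOCABULARY = PCG_LABELS + TRNA_LABELS + RRNA_LABELS + ("CR", "OL")


def feature_class_of(label: str) -> str:
    """Return the feature class (PCG/tRNA/rRNA/CR/OL) of a canonical label."""
    if label in PCG_LABELS:
        return "PCG"
    if label in TRNA_LABELS:
        return "tRNA"
    if label in RRNA_LABELS:
        return "rRNA"
    if label in ("CR", "OL"):
        return label
    raise GeneNameError(f"{label!r} is not in the gene vocabulary")


def _canon_key(raw: str) -> str:
    return "".join(raw.split()).replace("_", "").lower()


def _build_synonyms() -> dict[str, str]:
    syn: dict[str, str] = {}

    def add(label: str, *names: str) -> None:
        for n in (label, *names):
            syn[_canon_key(n)] = label

    add("ND1", "nad1", "nadh1", "NADH dehydrogenase subunit 1")
    add("ND2", "nad2", "nadh2", "NADH dehydrogenase subunit 2")
    add("ND3", "nad3", "nadh3", "NADH dehydrogenase subunit 3")
    add("ND4", "nad4", "nadh4", "NADH dehydrogenase subunit 4")
    add("ND4L", "nad4l", "nadh4l", "NADH dehydrogenase subunit 4L")
    add("ND5", "nad5", "nadh5", "NADH dehydrogenase subunit 5")
    add("ND6", "nad6", "nadh6", "NADH dehydrogenase subunit 6")
    add("COX1", "COI", "CO1", "coxI", "cytochrome c oxidase subunit I",
        "cytochrome c oxidase subunit 1")
    add("COX2", "COII", "CO2", "coxII", "cytochrome c oxidase subunit II",
        "cytochrome c oxidase subunit 2")
    add("COX3", "COIII", "CO3", "coxIII", "cytochrome c oxidase subunit III",
        "cytochrome c oxidase subunit 3")
    add("ATP6", "ATPase6", "ATPase 6", "ATP synthase F0 subunit 6")
    add("ATP8", "ATPase8", "ATPase 8", "ATP synthase F0 subunit 8")
    add("CYTB", "cob", "cytb", "cyt b", "cytochrome b")
    add("rrnS", "12S", "12S rRNA", "12S ribosomal RNA", "s-rRNA", "srRNA",
        "small subunit ribosomal RNA", "MT-RNR1", "rrn12")
    add("rrnL", "16S", "16S rRNA", "16S ribosomal RNA", "l-rRNA", "lrRNA",
        "large subunit ribosomal RNA", "MT-RNR2", "rrn16")
    add("CR", "D-loop", "dloop", "control region", "putative control region",
        "misc control region")
    add("OL", "rep_origin", "oriL", "origin of L-strand replication",
        "L-strand replication origin", "light strand replication origin",
        "light-strand replication origin")

    one_letter = {
        "Phe": "F", "Val": "V", "Ile": "I", "Gln": "Q", "Met": "M",
        "Trp": "W", "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y",
        "Asp": "D", "Lys": "K", "Gly": "G", "Arg": "R", "His": "H",
        "Glu": "E", "Thr": "T", "Pro": "P",
    }
    for aa, letter in one_letter.items():
        add(f"tRNA-{aa}", f"trn{letter}", f"tRNA {aa}", f"tRNA_{aa}")
    # isoacceptor-split leucine and serine
    add("tRNA-Leu1", "trnL1", "tRNA-Leu(CUN)", "tRNA-Leu (CUN)",
        "trnL(tag)", "tRNA-Leu1(CUN)")
    add("tRNA-Leu2", "trnL2", "tRNA-Leu(UUR)", "tRNA-Leu (UUR)",
        "trnL(taa)", "tRNA-Leu2(UUR)")
    add("tRNA-Ser1", "trnS1", "tRNA-Ser(AGY)", "tRNA-Ser (AGY)",
        "trnS(gct)", "tRNA-Ser1(AGY)")
    add("tRNA-Ser2", "trnS2", "tRNA-Ser(UCN)", "tRNA-Ser (UCN)",
        "trnS(tga)", "tRNA-Ser2(UCN)")
    return syn


_SYNONYMS = _build_synonyms()


def normalize_gene_name(raw: str) -> "GeneName":
    """Map a raw annotation name (any common dialect) to a :class:`GeneName`.

    Matching is case-insensitive and ignores spaces/underscores, so
    ``"tRNA-Ser (UCN)"``, ``"trnS2"`` and ``"TRNA-SER(UCN)"`` all resolve to
    ``tRNA-Ser2``.  Unknown names raise :class:`GeneNameError` listing the
    nearest vocabulary entries.
    """
    if not raw or not raw.strip():
        raise GeneNameError("empty gene name")
    key = _canon_key(raw)
    label = _SYNONYMS.get(key)
    if label is None:
        near = difflib.get_close_matches(key, _SYNONYMS.keys(), n=3, cutoff=0.5)
        hints = sorted({_SYNONYMS[k] for k in near})
        raise GeneNameError(
            f"unknown gene name {raw!r}; nearest vocabulary entries: {hints}"
        )
    return GeneName(label)


@dataclass(frozen=True, order=True)
class GeneName:
    """A gene identity drawn from the closed mitochondrial vocabulary."""

    canonical_label: str

    def __post_init__(self) -> None:
        if self.canonical_label not in VOCABULARY:
            raise GeneNameError(
                f"{self.canonical_label!r} is not a canonical label; "
                f"use normalize_gene_name() for raw annotation names"
            )

    @property
    def feature_class(self) -> str:
        return feature_class_of(self.canonical_label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_label


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length for an origin-spanning feature.  ``strand`` is +1 for the heavy
    strand, -1 for the light strand.  ``copy_label`` ('a', 'b', ...) is set
    only when the record carries multiple copies of the same gene.
    """

    name: GeneName
    start: int
    end: int
    strand: int = 1
    copy_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) for {self.name}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start


def feature_length(feature: GeneFeature, genome_length: int) -> int:
    """Length of a feature in bp; origin wrapping is already unwrapped."""
    if feature.end - feature.start > genome_length:
        raise ValueError(
            f"feature {feature.name} longer than genome ({genome_length} bp)"
        )
    return feature.end - feature.start


def assign_copy_labels(features: Sequence[GeneFeature]) -> list[GeneFeature]:
    """Assign copy labels a, b, c ... in genome order (from position 0).

    Genes present once get ``copy_label=None``; duplicated genes are lettered
    by ascending start coordinate, mirroring the CR I/II/III convention.
    """
    ordered = sorted(features, key=lambda f: (f.start, -(f.end - f.start)))
    counts: dict[str, int] = {}
    for f in ordered:
        counts[f.name.canonical_label] = counts.get(f.name.canonical_label, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for f in ordered:
        label = f.name.canonical_label
        if counts[label] > 1:
            idx = seen.get(label, 0)
            seen[label] = idx + 1
            out.append(replace(f, copy_label=chr(ord("a") + idx)))
        else:
            out.append(replace(f, copy_label=None))
    return out


@dataclass
class MitogenomeRecord:
    """A circular annotated mitogenome."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_complete: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty sequence")
        for f in self.features:
            if f.start >= n:
                raise ValueError(f"feature {f.name} starts beyond genome end")
            if f.end - f.start > n:
                raise ValueError(f"feature {f.name} longer than the genome")
        # stable order: by start, longer feature first on ties
        self.features = sorted(
            self.features, key=lambda f: (f.start, -(f.end - f.start))
        )
        self._check_copy_labels()

    def _check_copy_labels(self) -> None:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.name.canonical_label] = counts.get(f.name.canonical_label, 0) + 1
        for f in self.features:
            dup = counts[f.name.canonical_label] > 1
            if dup and f.copy_label is None:
                raise ValueError(
                    f"duplicated gene {f.name} missing copy_label; "
                    f"use assign_copy_labels()"
                )
            if not dup and f.copy_label is not None:
                raise ValueError(f"single-copy gene {f.name} carries a copy_label")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Feature sequence on its coding strand (handles origin wrapping)."""
        n = self.length
        if feature.end <= n:
            s = self.sequence[feature.start:feature.end]
        else:
            s = self.sequence[feature.start:] + self.sequence[: feature.end - n]
        if feature.strand == -1:
            s = str(Seq(s).reverse_complement())
        return s

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name.feature_class == feature_class]


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_SKIPPED_TYPES_OF_INTEREST = {"CDS", "tRNA", "rRNA", "D-loop", "rep_origin",
                              "misc_feature"}


def _raw_feature_name(feat: SeqFeature) -> Optional[str]:
    if feat.type == "D-loop":
        return feat.qualifiers.get("note", ["D-loop"])[0] or "D-loop"
    if feat.type == "rep_origin":
        return feat.qualifiers.get("note", ["OL"])[0] or "OL"
    for key in ("gene", "product", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals and vals[0].strip():
            return vals[0]
    return None


def _convert_location(feat: SeqFeature, genome_length: int):
    """Internal (start, end, strand); join() across the origin is unwrapped."""
    loc = feat.location
    strand = int(loc.strand or 1)
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 2:
        by_start = {int(p.start): p for p in parts}
        if 0 in by_start and any(int(p.end) == genome_length for p in parts):
            head = next(p for p in parts if int(p.end) == genome_length)
            tail = by_start[0]
            if head is not tail:
                return int(head.start), genome_length + int(tail.end), strand
    if len(parts) > 1:
        raise ValueError("complex multi-part location")
    return int(loc.start), int(loc.end), strand


def read_genbank(path, *, skipped: Optional[list] = None) -> list[MitogenomeRecord]:
    """Parse a GenBank flat file into :class:`MitogenomeRecord` objects.

    Features whose names cannot be mapped to the vocabulary (or whose
    locations are too complex) are appended to ``skipped`` as
    ``(record_id, raw_name, location_string)`` tuples instead of aborting
    the record — deposited annotations are frequently inconsistent.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenBankFormatError(f"cannot parse {path}: {exc}") from exc
    if not seq_records:
        raise EmptyInputError(f"no GenBank records found in {path}")

    records = []
    for rec in seq_records:
        genome_length = len(rec.seq)
        feats: list[GeneFeature] = []
        for feat in rec.features:
            if feat.type not in _SKIPPED_TYPES_OF_INTEREST:
                continue
            raw = _raw_feature_name(feat)
            try:
                if raw is None:
                    raise GeneNameError("feature without a name qualifier")
                name = normalize_gene_name(raw)
                start, end, strand = _convert_location(feat, genome_length)
            except (GeneNameError, ValueError):
                if skipped is not None:
                    skipped.append((rec.name or rec.id, raw or "", str(feat.location)))
                continue
            feats.append(GeneFeature(name=name, start=start, end=end, strand=strand))
        desc = (rec.description or "").lower()
        records.append(
            MitogenomeRecord(
                identifier=rec.name or rec.id,
                sequence=str(rec.seq),
                features=assign_copy_labels(feats),
                is_complete=not ("nearly complete" in desc or "partial" in desc),
            )
        )
    return records


_WRITE_TYPES = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "CR": "D-loop", "OL": "rep_origin"}


def _to_seqfeature(f: GeneFeature, genome_length: int) -> SeqFeature:
    if f.end <= genome_length:
        loc = SimpleLocation(f.start, f.end, strand=f.strand)
    else:
        loc = CompoundLocation([
            SimpleLocation(f.start, genome_length, strand=f.strand),
            SimpleLocation(0, f.end - genome_length, strand=f.strand),
        ])
    ftype = _WRITE_TYPES[f.name.feature_class]
    quals: dict[str, list[str]] = {"gene": [f.name.canonical_label]}
    if f.name.feature_class == "PCG":
        quals["transl_table"] = ["2"]
    if f.name.feature_class == "CR":
        quals = {"note": ["control region"]}
    if f.name.feature_class == "OL":
        quals = {"note": ["origin of L-strand replication"]}
    if f.copy_label:
        quals.setdefault("note", []).append(f"copy {f.copy_label}")
    return SeqFeature(location=loc, type=ftype, qualifiers=quals)


def write_genbank(records: Sequence[MitogenomeRecord], path) -> None:
    """Write records as a GenBank flat file losslessly re-readable by
    :func:`read_genbank`."""
    if not records:
        raise EmptyInputError("refusing to write an empty record list")
    out = []
    for r in records:
        seq_rec = SeqRecord(
            Seq(r.sequence),
            id=r.identifier,
            name=r.identifier[:16],
            description="mitochondrial genome, "
            + ("complete" if r.is_complete else "nearly complete"),
        )
        seq_rec.annotations["molecule_type"] = "DNA"
        seq_rec.annotations["topology"] = "circular"
        seq_rec.features = [_to_seqfeature(f, r.length) for f in r.features]
        out.append(seq_rec)
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "genbank")


def write_skipped_log(entries: Iterable[tuple], path) -> None:
    """Write the skipped-features log as TSV (record id, raw name, location)."""
    with open(path, "w") as fh:
        fh.write("record_id\traw_name\tlocation\n")
        for rec_id, raw, loc in entries:
            fh.write(f"{rec_id}\t{raw}\t{loc}\n")


def write_feature_fasta(record: MitogenomeRecord, path,
                        labels: Optional[set[str]] = None) -> int:
    """Export feature sequences (coding strand) as FASTA; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for f in record.features:
            if labels is not None and f.name.canonical_label not in labels:
                continue
            copy = f"_{f.copy_label}" if f.copy_label else ""
            fh.write(f">{record.identifier}|{f.name.canonical_label}{copy}\n")
            fh.write(record.feature_sequence(f) + "\n")
            n += 1
    return n


def apply_annotation_patch(record: MitogenomeRecord, patch: dict) -> MitogenomeRecord:
    """Apply a user-supplied annotation patch to a record.

    ``patch`` is a mapping with optional keys:

    - ``"drop"``: list of ``{"label": ..., "copy": ...}`` selectors (``copy``
      optional) removing features — e.g. discarding a mis-annotated tRNA that
      re-annotation showed to be control-region sequence;
    - ``"add"``: list of ``{"label", "start", "end", "strand"}`` features.

    Copy labels are reassigned after patching.
    """
    feats = list(record.features)
    for sel in patch.get("drop", []):
        label = normalize_gene_name(sel["label"]).canonical_label
        copy = sel.get("copy")
        feats = [
            f for f in feats
            if not (f.name.canonical_label == label
                    and (copy is None or f.copy_label == copy))
        ]
    for spec in patch.get("add", []):
        feats.append(
            GeneFeature(
                name=normalize_gene_name(spec["label"]),
                start=int(spec["start"]),
                end=int(spec["end"]),
                strand=int(spec.get("strand", 1)),
            )
        )
    return MitogenomeRecord(
        identifier=record.identifier,
        sequence=record.sequence,
        features=assign_copy_labels([replace(f, copy_label=None) for f in feats]),
        is_complete=record.is_complete,
    )
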
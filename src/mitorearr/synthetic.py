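"""Synthetic annotated mitogenomes with known ground truth.

The generator lays out a complete circular vertebrate-style mitogenome —
13 protein-coding genes, 22 tRNAs (plus any duplicates implied by the
requested arrangement), two rRNAs and one to three control regions — whose
gene order is the canonical vertebrate order with a chosen TDRL-derived
hotspot arrangement substituted between tRNA-Thr and 12S rRNA.  Background
sequence is drawn i.i.d. from configurable base frequencies; on top of it
the generator stamps the features that downstream statistics depend on:
vertebrate-mitochondrial start/stop codons per gene (including the
incomplete ``T--`` stops completed by polyadenylation), the CSB1 motif
``CTTTTCATGCTCAGTAGACATA`` in every control region, reverse-complemented
content for light-strand genes, and a 13 bp ND5/ND6 overlap mirroring the
longest overlap reported for these genomes.

Every record is paired with a :class:`TruthManifest` carrying the intended
gene order, coordinates and generating parameters, so round-trip tests
(extraction, classification, GenBank I/O) can assert against ground truth.
Defaults emulate the published *P. helioscopus* genomes: whole-genome
A+T ~62.4% with positive AT-skew and strongly negative GC-skew, ~11.3 kb
of protein-coding sequence, 70 bp tRNAs, 867/1485 bp rRNAs, and the
reported control-region lengths per arrangement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .gene_order import ArrangementType, default_registry
from .mito_io import (GeneFeature, MitogenomeRecord, assign_copy_labels,
                      normalize_gene_name)
from .tdrl import TDRLScenario, apply_scenario

__all__ = [
    "SyntheticSpec",
    "TruthManifest",
    "CSB1_MOTIF",
    "CANONICAL_GENE_ORDER",
    "L_STRAND_GENES",
    "full_gene_order",
    "generate_record",
    "mutate_copy",
    "load_spec",
    "packaged_spec",
]

CSB1_MOTIF = "CTTTTCATGCTCAGTAGACATA"

#: genes encoded on the light strand: ND6 and eight tRNAs
L_STRAND_GENES = frozenset({
    "ND6", "tRNA-Pro", "tRNA-Gln", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys",
    "tRNA-Tyr", "tRNA-Ser2", "tRNA-Glu",
})

#: canonical vertebrate mitochondrial gene order, rotated to start at the
#: 12S rRNA anchor; the hotspot (tRNA-Pro, CR, tRNA-Phe) sits at the end,
#: immediately before the circle closes back to 12S
CANONICAL_GENE_ORDER: tuple[str, ...] = (
    "rrnS", "tRNA-Val", "rrnL", "tRNA-Leu2", "ND1", "tRNA-Ile", "tRNA-Gln",
    "tRNA-Met", "ND2", "tRNA-Trp", "tRNA-Ala", "tRNA-Asn", "OL", "tRNA-Cys",
    "tRNA-Tyr", "COX1", "tRNA-Ser2", "tRNA-Asp", "COX2", "tRNA-Lys", "ATP8",
    "ATP6", "COX3", "tRNA-Gly", "ND3", "tRNA-Arg", "ND4L", "ND4", "tRNA-His",
    "tRNA-Ser1", "tRNA-Leu1", "ND5", "ND6", "tRNA-Glu", "CYTB", "tRNA-Thr",
    "tRNA-Pro", "CR", "tRNA-Phe",
)

CANONICAL_HOTSPOT: tuple[str, ...] = ("tRNA-Pro", "CR", "tRNA-Phe")

#: default gene lengths (bp); protein genes sum to ~11.3 kb and each length
#: is congruent mod 3 with its stop-codon convention below
_PCG_LENGTHS = {
    "ND1": 975, "ND2": 1035, "COX1": 1551, "COX2": 688, "ATP8": 168,
    "ATP6": 685, "COX3": 784, "ND3": 346, "ND4L": 297, "ND4": 1380,
    "ND5": 1815, "ND6": 516, "CYTB": 1141,
}
#: initiation codons: GTG for ATP8/ND4L/ND6, ATG otherwise
_START_CODONS = {g: ("GTG" if g in ("ATP8", "ND4L", "ND6") else "ATG")
                 for g in _PCG_LENGTHS}
#: termination: AGA for ND2/COX1, AGG for ND6, incomplete T-- for
#: COX2/ATP6/COX3/ND3/CYTB, TAA otherwise
_STOP_CODONS = {g: "TAA" for g in _PCG_LENGTHS}
_STOP_CODONS.update({"ND2": "AGA", "COX1": "AGA", "ND6": "AGG",
                     "COX2": "T", "ATP6": "T", "COX3": "T", "ND3": "T",
                     "CYTB": "T"})

_RRNA_LENGTHS = {"rrnS": 867, "rrnL": 1485}
#: control-region lengths by arrangement, in hotspot order (CR I, II, III)
_CR_LENGTHS = {"typical": (893,), "V": (892, 334), "IX": (893, 804, 417)}
_CR_DEFAULT = 850

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic mitogenome.

    Default base frequencies reproduce the composition scale reported for
    these genomes (A+T 62.4%, AT-skew ~+0.06, GC-skew ~-0.29).
    """

    base_freqs: tuple[float, float, float, float] = (0.332, 0.243, 0.133, 0.292)  # A C G T
    genome_scale: Optional[int] = None
    arrangement: Union[str, TDRLScenario] = "typical"
    iqm_or_qim: Optional[str] = None  # default: registry entry's state, or IQM
    pcg_lengths: dict = field(default_factory=lambda: dict(_PCG_LENGTHS))
    trna_length: int = 70
    rrna_lengths: dict = field(default_factory=lambda: dict(_RRNA_LENGTHS))
    cr_lengths: Optional[tuple[int, ...]] = None
    start_codons: dict = field(default_factory=lambda: dict(_START_CODONS))
    stop_codons: dict = field(default_factory=lambda: dict(_STOP_CODONS))
    nd5_nd6_overlap: int = 13
    max_spacer: int = 2
    include_ol: bool = False
    seed: int = 0
    identifier: Optional[str] = None

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.trna_length <= 0 or any(v <= 0 for v in self.pcg_lengths.values()):
            raise ValueError("feature lengths must be positive")


@dataclass
class TruthManifest:
    """Ground truth emitted alongside a generated record."""

    gene_order: list[tuple]  # (label, strand, copy_label)
    coordinates: dict  # "label[copy]" -> (start, end, strand)
    base_freqs: tuple
    arrangement: str
    seed: int

    def to_json(self) -> dict:
        return {
            "gene_order": [list(t) for t in self.gene_order],
            "coordinates": {k: list(v) for k, v in self.coordinates.items()},
            "base_freqs": list(self.base_freqs),
            "arrangement": self.arrangement,
            "seed": self.seed,
        }


def _registry_entry(label: str) -> ArrangementType:
    for entry in default_registry():
        if entry.label == label:
            return entry
    raise KeyError(f"unknown arrangement label {label!r}; "
                   f"supply a TDRLScenario or extend the registry")


def full_gene_order(arrangement: Union[str, TDRLScenario],
                    iqm_or_qim: Optional[str] = None,
                    include_ol: bool = False) -> list[tuple[str, int]]:
    """Whole-genome (label, strand) list for an arrangement.

    The canonical order's hotspot tail (tRNA-Pro, CR, tRNA-Phe) is replaced
    by the arrangement's hotspot, and the Ile/Gln tRNAs are swapped when the
    arrangement carries the derived QIM cluster.
    """
    if isinstance(arrangement, str):
        entry = _registry_entry(arrangement)
        hotspot = list(entry.hotspot)
        iqm = iqm_or_qim or entry.iqm_or_qim
    else:
        hotspot = apply_scenario(arrangement)
        iqm = iqm_or_qim or "IQM"

    body = [g for g in CANONICAL_GENE_ORDER if g not in CANONICAL_HOTSPOT]
    if not include_ol:
        body = [g for g in body if g != "OL"]
    order = body + hotspot
    if iqm == "QIM":
        i, q = order.index("tRNA-Ile"), order.index("tRNA-Gln")
        order[i], order[q] = order[q], order[i]
    elif iqm != "IQM":
        raise ValueError(f"unsupported I/Q/M cluster state {iqm!r}")
    return [(g, -1 if g in L_STRAND_GENES else 1) for g in order]


def _feature_lengths(spec: SyntheticSpec, order: list[tuple[str, int]],
                     arrangement_key: str) -> list[int]:
    cr_lengths = spec.cr_lengths or _CR_LENGTHS.get(arrangement_key)
    cr_iter = iter(cr_lengths or ())
    out = []
    for label, _ in order:
        if label in spec.pcg_lengths:
            out.append(spec.pcg_lengths[label])
        elif label.startswith("tRNA-"):
            out.append(spec.trna_length)
        elif label in spec.rrna_lengths:
            out.append(spec.rrna_lengths[label])
        elif label == "CR":
            out.append(next(cr_iter, _CR_DEFAULT))
        elif label == "OL":
            out.append(35)
        else:  # pragma: no cover - vocabulary is closed
            raise ValueError(f"no length rule for {label}")
    return out


def generate_record(spec: SyntheticSpec) -> tuple[MitogenomeRecord, TruthManifest]:
    """Build a synthetic annotated mitogenome and its truth manifest.

    Deterministic: two calls with the same spec (including seed) produce
    byte-identical records.
    """
    rng = np.random.default_rng(spec.seed)
    arrangement_key = (spec.arrangement if isinstance(spec.arrangement, str)
                       else "scenario")
    order = full_gene_order(spec.arrangement, spec.iqm_or_qim, spec.include_ol)
    lengths = _feature_lengths(spec, order, arrangement_key)

    # layout: small random spacers; fixed ND5/ND6 overlap
    feats: list[GeneFeature] = []
    cursor = 0
    prev_label = None
    for (label, strand), length in zip(order, lengths):
        if prev_label == "ND5" and label == "ND6":
            gap = -spec.nd5_nd6_overlap
        elif prev_label is None:
            gap = 0
        else:
            gap = int(rng.integers(0, spec.max_spacer + 1))
        start = cursor + gap
        feats.append(GeneFeature(name=normalize_gene_name(label),
                                 start=start, end=start + length,
                                 strand=strand))
        cursor = start + length
        prev_label = label
    genome_length = cursor
    if spec.genome_scale is not None:
        if spec.genome_scale < genome_length:
            raise ValueError(
                f"genome_scale {spec.genome_scale} smaller than the "
                f"{genome_length} bp needed by the feature layout"
            )
        genome_length = spec.genome_scale

    seq = rng.choice(np.array(list("ACGT")), size=genome_length,
                     p=list(spec.base_freqs))

    def stamp(pos: int, s: str) -> None:
        seq[pos:pos + len(s)] = list(s)

    for f in feats:
        label = f.name.canonical_label
        if f.name.feature_class == "PCG":
            start_codon = spec.start_codons[label]
            stop = spec.stop_codons[label]
            if len(stop) == 3 and f.length % 3 != 0:
                raise ValueError(f"{label}: complete stop needs length % 3 == 0")
            if len(stop) < 3 and f.length % 3 != len(stop):
                raise ValueError(f"{label}: incomplete stop {stop!r} needs "
                                 f"length % 3 == {len(stop)}")
            if f.strand == 1:
                stamp(f.start, start_codon)
                stamp(f.end - len(stop), stop)
            else:
                stamp(f.end - 3, _revcomp(start_codon))
                stamp(f.start, _revcomp(stop))
        elif label == "CR":
            stamp(f.start + min(20, f.length - len(CSB1_MOTIF)), CSB1_MOTIF)

    record = MitogenomeRecord(
        identifier=spec.identifier
        or f"SYN{arrangement_key.upper()[:8]}S{spec.seed}",
        sequence="".join(seq),
        features=assign_copy_labels(feats),
        is_complete=True,
    )
    manifest = TruthManifest(
        gene_order=[(f.name.canonical_label, f.strand, f.copy_label)
                    for f in record.features],
        coordinates={
            f.name.canonical_label + (f"({f.copy_label})" if f.copy_label else ""):
            (f.start, f.end, f.strand)
            for f in record.features
        },
        base_freqs=spec.base_freqs,
        arrangement=arrangement_key,
        seed=spec.seed,
    )
    return record, manifest


def mutate_copy(record: MitogenomeRecord, per_site_rate: float,
                seed: int) -> MitogenomeRecord:
    """An independently mutated copy of a record (annotation preserved).

    Each site substitutes with probability ``per_site_rate``, uniformly
    among the three alternative bases, so the expected p-distance to the
    original is the rate itself (every substitution changes the base).
    """
    if not 0 <= per_site_rate < 1:
        raise ValueError("per-site rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = np.array(list(record.sequence))
    hits = np.nonzero(rng.random(len(seq)) < per_site_rate)[0]
    alternatives = {b: [x for x in "ACGT" if x != b] for b in "ACGTN"}
    alternatives["N"] = ["N"]
    for pos in hits:
        seq[pos] = alternatives[seq[pos]][int(rng.integers(0, 3))]
    return MitogenomeRecord(
        identifier=record.identifier + "_mut",
        sequence="".join(seq),
        features=list(record.features),
        is_complete=record.is_complete,
    )


def load_spec(path) -> SyntheticSpec:
    """Load a generator spec from JSON (unknown keys rejected)."""
    with open(path) as fh:
        data = json.load(fh)
    kwargs = dict(data)
    for key in ("base_freqs", "cr_lengths"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticSpec(**kwargs)


def packaged_spec(name: str, **overrides) -> SyntheticSpec:
    """One of the shipped spec files: ``typical``, ``type_v``, ``type_ix``."""
    from importlib import resources
    ref = resources.files("mitorearr.data") / f"spec_{name}.json"
    with resources.as_file(ref) as path:
        spec = load_spec(path)
    return replace(spec, **overrides) if overrides else spec
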
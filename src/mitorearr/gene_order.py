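"""Circular gene orders, arrangement-type classification and diagnostics.

A :class:`GeneOrder` is the circular sequence of gene tokens of one
mitogenome, canonicalized by rotation so that a single-copy anchor gene
(12S rRNA by default) comes first.  Orders are classified against a
registry of named arrangement types by exact token matching of the
*hotspot segment* — the run of genes strictly between tRNA-Thr and 12S
rRNA (tRNA-Pro, control regions, tRNA-Phe), where all of the rearrangement
variation discussed for toad-headed agamas is confined — combined with the
state of the Ile/Gln/Met tRNA cluster (ancestral IQM vs derived QIM).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .mito_io import MitogenomeRecord, normalize_gene_name

__all__ = [
    "GeneOrderToken",
    "GeneOrder",
    "ArrangementType",
    "ArrangementCall",
    "AnchorError",
    "extract_gene_order",
    "hotspot_segment",
    "diagnostics",
    "classify",
    "count_distinct_types",
    "load_registry",
    "default_registry",
]


class AnchorError(ValueError):
    """Anchor gene missing or duplicated in an order."""


@dataclass(frozen=True)
class GeneOrderToken:
    label: str
    strand: int = 1
    copy_label: Optional[str] = None


@dataclass(frozen=True)
class GeneOrder:
    """A circular gene order, stored rotated so the anchor token is first."""

    tokens: tuple[GeneOrderToken, ...]
    anchor: str = "rrnS"

    def __post_init__(self) -> None:
        idx = [i for i, t in enumerate(self.tokens) if t.label == self.anchor]
        if len(idx) != 1:
            singles = sorted({
                t.label for t in self.tokens
                if sum(u.label == t.label for u in self.tokens) == 1
            })
            raise AnchorError(
                f"anchor {self.anchor!r} occurs {len(idx)} times; "
                f"single-copy candidates: {singles}"
            )
        k = idx[0]
        if k:
            object.__setattr__(self, "tokens",
                               self.tokens[k:] + self.tokens[:k])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)

    def count(self, label: str) -> int:
        return sum(t.label == label for t in self.tokens)


def extract_gene_order(record: MitogenomeRecord, anchor: str = "rrnS") -> GeneOrder:
    """Gene order of a record, in genome order starting at the anchor."""
    tokens = tuple(
        GeneOrderToken(f.name.canonical_label, f.strand, f.copy_label)
        for f in record.features
    )
    return GeneOrder(tokens=tokens, anchor=anchor)


def hotspot_segment(order: GeneOrder) -> list[GeneOrderToken]:
    """Tokens strictly between tRNA-Thr and 12S rRNA, walking forward.

    With the order canonically rotated (12S first), this is everything
    after the single tRNA-Thr token through the end of the circle.
    """
    if order.count("tRNA-Thr") != 1:
        raise AnchorError("hotspot bounds require exactly one tRNA-Thr")
    t_idx = order.labels.index("tRNA-Thr")
    return list(order.tokens[t_idx + 1:])


@dataclass(frozen=True)
class ArrangementType:
    label: str
    iqm_or_qim: str  # "IQM" | "QIM"
    hotspot: tuple[str, ...]
    description: str = ""


@dataclass
class ArrangementCall:
    matched_label: str  # registry label or "novel"
    diagnostics: dict = field(default_factory=dict)


def diagnostics(order: GeneOrder) -> dict:
    """The three rearrangement diagnostics plus copy counts.

    - ``iqm_or_qim``: relative order of the Ile/Gln/Met tRNA cluster;
    - ``trnP_position``: position class of tRNA-Pro within the hotspot
      relative to tRNA-Phe and the control regions (``before-F``,
      ``after-F``, ``between-CRs``, or ``absent``);
    - ``trnF_copies`` and ``cr_copies``.
    """
    labels = order.labels
    diag: dict = {
        "trnF_copies": order.count("tRNA-Phe"),
        "cr_copies": order.count("CR"),
    }

    cluster = [(labels.index(g), letter) for g, letter in
               (("tRNA-Ile", "I"), ("tRNA-Gln", "Q"), ("tRNA-Met", "M"))
               if g in labels]
    if len(cluster) < 3:
        diag["iqm_or_qim"] = "absent"
    else:
        diag["iqm_or_qim"] = "".join(letter for _, letter in sorted(cluster))

    try:
        hotspot = [t.label for t in hotspot_segment(order)]
    except AnchorError:
        hotspot = []
    diag["trnP_position"] = _trnP_position(hotspot)
    return diag


def _trnP_position(hotspot_labels: Sequence[str]) -> str:
    if "tRNA-Pro" not in hotspot_labels or "tRNA-Phe" not in hotspot_labels:
        return "absent"
    p = hotspot_labels.index("tRNA-Pro")
    before, after = hotspot_labels[:p], hotspot_labels[p + 1:]
    if ("CR" in before and "tRNA-Phe" in before
            and "CR" in after and "tRNA-Phe" in after):
        return "between-CRs"
    return "before-F" if "tRNA-Phe" in after else "after-F"


def classify(order: GeneOrder,
             registry: Sequence[ArrangementType]) -> ArrangementCall:
    """Match an order against the registry; no match yields ``"novel"``.

    Matching compares the hotspot token labels (copy labels and strands
    ignored — none of the registered types involve inversions) plus the
    I/Q/M cluster state; the first matching registry entry wins.
    """
    if not registry:
        raise ValueError("empty arrangement registry")
    diag = diagnostics(order)
    try:
        hotspot = tuple(t.label for t in hotspot_segment(order))
    except AnchorError:
        hotspot = ()
    for entry in registry:
        if hotspot == entry.hotspot and diag["iqm_or_qim"] == entry.iqm_or_qim:
            return ArrangementCall(entry.label, diag)
    return ArrangementCall("novel", diag)


def count_distinct_types(orders: Sequence[GeneOrder],
                         registry: Sequence[ArrangementType]):
    """Group orders by arrangement call; returns (count, partition).

    Novel orders are grouped by their exact hotspot label sequence (plus
    I/Q/M state), so two identical unregistered orders count as one type.
    """
    if not orders:
        raise ValueError("need at least one gene order")
    partition: dict = {}
    for i, order in enumerate(orders):
        call = classify(order, registry)
        if call.matched_label != "novel":
            key = call.matched_label
        else:
            try:
                hs = tuple(t.label for t in hotspot_segment(order))
            except AnchorError:
                hs = order.labels
            key = ("novel", hs, call.diagnostics["iqm_or_qim"])
        partition.setdefault(key, []).append(i)
    return len(partition), partition


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _parse_registry_rows(rows: Iterable[dict]) -> list[ArrangementType]:
    out: list[ArrangementType] = []
    seen = set()
    for row in rows:
        label = row["label"].strip()
        if label in seen:
            raise ValueError(f"duplicate registry label {label!r}")
        seen.add(label)
        iqm = row["iqm_or_qim"].strip().upper()
        if sorted(iqm) != ["I", "M", "Q"]:
            raise ValueError(f"bad I/Q/M cluster spec {iqm!r} for {label!r}")
        tokens = tuple(
            normalize_gene_name(tok).canonical_label
            for tok in row["hotspot"].split(",") if tok.strip()
        )
        out.append(ArrangementType(label, iqm, tokens,
                                   row.get("description", "") or ""))
    if not out:
        raise ValueError("registry file contains no entries")
    return out


def load_registry(path) -> list[ArrangementType]:
    """Load an arrangement-type registry from TSV.

    Columns: ``label``, ``iqm_or_qim``, ``hotspot`` (comma-separated gene
    tokens between tRNA-Thr and 12S rRNA), optional ``description``.
    """
    with open(path, newline="") as fh:
        return _parse_registry_rows(csv.DictReader(fh, delimiter="\t"))


def default_registry() -> list[ArrangementType]:
    """The shipped registry: the typical vertebrate order plus the two
    *P. helioscopus* arrangements (types V and IX); further types can be
    supplied through a registry file."""
    ref = resources.files("mitorearr.data") / "registry.tsv"
    with resources.as_file(ref) as path:
        return load_registry(path)
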
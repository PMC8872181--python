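"""Tandem duplication / random loss (TDRL) modelling on a linear gene segment.

Under the TDRL model a contiguous block of genes is duplicated in tandem
and redundant copies are subsequently lost, leaving a new gene order.  All
rearrangement variation described for *Phrynocephalus helioscopus* is
confined to the hotspot segment between tRNA-Thr and 12S rRNA, so the model
here operates on a short *linear* token list (the segment between those
fixed anchors), which keeps the combinatorics small and exact.

An event duplicates the block at inclusive indices ``[i, j]`` and removes a
loss set.  Losses come in two flavours:

* in-block losses, named ``("orig" | "dup", offset)`` over the 2L copy
  positions created by the duplication — the only losses the scenario
  *search* enumerates;
* optional segment-level losses (absolute indices into the post-duplication
  segment) for random losses falling outside the duplicated block, needed to
  encode the published pathway literally (its final step deletes a
  tRNA-Phe copy created by an *earlier* duplication).

Essentiality: every gene name other than the control region (``CR``) that
is present before an event must retain at least one copy afterwards; CR
copies may be freely gained or lost.  The loss set may be empty — that is
how a retained extra tRNA-Phe or supernumerary control region arises.

Cost of a scenario = number of duplication events; losses are free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "TDRLEvent",
    "TDRLScenario",
    "SearchConfig",
    "MinimalScenarios",
    "InvalidEventError",
    "ScenarioError",
    "SegmentSizeError",
    "apply_event",
    "apply_scenario",
    "validate_scenario",
    "search_min_scenarios",
    "enumerate_events",
    "copy_labelled",
    "render_segment",
    "load_scenario",
    "packaged_scenario",
]

Token = str
FREE_TOKENS = frozenset({"CR"})


class InvalidEventError(ValueError):
    """An event would extinguish an essential gene or is out of bounds."""


class ScenarioError(ValueError):
    """A scenario's start order does not match the segment it is applied to."""


class SegmentSizeError(ValueError):
    """A segment exceeds the configured search bound."""


@dataclass(frozen=True)
class TDRLEvent:
    """One tandem duplication of ``block=[i, j]`` followed by losses."""

    block: tuple[int, int]
    losses: frozenset[tuple[str, int]] = frozenset()
    segment_losses: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        i, j = self.block
        if i < 0 or j < i:
            raise InvalidEventError(f"invalid block interval [{i}, {j}]")
        length = j - i + 1
        for which, off in self.losses:
            if which not in ("orig", "dup") or not 0 <= off < length:
                raise InvalidEventError(
                    f"loss ({which!r}, {off}) outside the duplicated block"
                )

    def loss_indices(self, segment_length: int) -> frozenset[int]:
        """Absolute indices removed from the post-duplication segment."""
        i, j = self.block
        length = j - i + 1
        idx = set()
        for which, off in self.losses:
            idx.add(i + off if which == "orig" else j + 1 + off)
        for k in self.segment_losses:
            if not 0 <= k < segment_length + length:
                raise InvalidEventError(
                    f"segment-level loss index {k} out of range"
                )
            if i <= k <= j + length:
                raise InvalidEventError(
                    f"segment-level loss index {k} lies inside the duplicated "
                    f"block; name it as ('orig'|'dup', offset) instead"
                )
            idx.add(k)
        return frozenset(idx)


def apply_event(segment: Sequence[Token], event: TDRLEvent,
                free_tokens: frozenset = FREE_TOKENS) -> list[Token]:
    """Apply one duplication + loss event; returns the new segment.

    Raises :class:`InvalidEventError` if the block is out of range or if an
    essential (non-CR) gene would lose its last copy.
    """
    seg = list(segment)
    i, j = event.block
    if j >= len(seg):
        raise InvalidEventError(
            f"block [{i}, {j}] out of range for segment of length {len(seg)}"
        )
    block = seg[i:j + 1]
    post = seg[:i] + block + block + seg[j + 1:]
    removed = event.loss_indices(len(seg))
    result = [tok for k, tok in enumerate(post) if k not in removed]
    before = set(seg) - free_tokens
    after = set(result)
    extinct = before - after
    if extinct:
        raise InvalidEventError(
            f"event extinguishes essential gene(s): {sorted(extinct)}"
        )
    return result


@dataclass(frozen=True)
class TDRLScenario:
    """An ordered series of TDRL events applied to a start segment."""

    start_order: tuple[Token, ...]
    events: tuple[TDRLEvent, ...] = ()
    name: str = ""

    def intermediate_states(self) -> list[tuple[Token, ...]]:
        states = [self.start_order]
        for ev in self.events:
            states.append(tuple(apply_event(states[-1], ev)))
        return states

    @property
    def end_order(self) -> tuple[Token, ...]:
        return self.intermediate_states()[-1]

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "start": list(self.start_order),
            "events": [
                {
                    "block": list(ev.block),
                    "losses": sorted([list(x) for x in ev.losses]),
                    "segment_losses": sorted(ev.segment_losses),
                }
                for ev in self.events
            ],
            "expected_end": list(self.end_order),
        }


def apply_scenario(scenario: TDRLScenario) -> list[Token]:
    """Sequentially apply every event; returns the final segment."""
    return list(scenario.end_order)


def validate_scenario(from_order: Sequence[Token], to_order: Sequence[Token],
                      scenario: TDRLScenario):
    """Check that a scenario transforms ``from_order`` into ``to_order``.

    Returns ``(ok, trace)`` where ``trace`` is the list of every segment
    state (start included).  Comparison ignores copy labels — states are
    plain gene-name tuples.  A mismatched start order is an error, not a
    ``False`` result.
    """
    if tuple(from_order) != tuple(scenario.start_order):
        raise ScenarioError(
            f"scenario starts from {list(scenario.start_order)}, "
            f"not {list(from_order)}"
        )
    trace = scenario.intermediate_states()
    return trace[-1] == tuple(to_order), trace


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    max_events: int = 3
    max_segment_length: int = 12
    free_tokens: frozenset = FREE_TOKENS

    def __post_init__(self) -> None:
        if self.max_events < 0 or self.max_segment_length <= 0:
            raise ValueError("search bounds must be positive")


def enumerate_events(segment: Sequence[Token],
                     config: SearchConfig) -> Iterator[tuple[TDRLEvent, tuple]]:
    """All valid in-block-loss events, in the deterministic order
    (block start ascending, block end ascending, loss mask as an ascending
    binary integer over the 2L copy positions: originals then duplicates)."""
    seg = list(segment)
    n = len(seg)
    for i in range(n):
        for j in range(i, n):
            length = j - i + 1
            for mask in range(1 << (2 * length)):
                losses = frozenset(
                    ("orig", k) if k < length else ("dup", k - length)
                    for k in range(2 * length)
                    if mask >> k & 1
                )
                if n + length - len(losses) > config.max_segment_length:
                    continue
                ev = TDRLEvent(block=(i, j), losses=losses)
                try:
                    res = tuple(apply_event(seg, ev, config.free_tokens))
                except InvalidEventError:
                    continue
                yield ev, res


def _is_subsequence(small: Sequence[Token], big: Sequence[Token]) -> Optional[list[int]]:
    """Leftmost embedding of ``small`` into ``big`` (indices) or ``None``."""
    out = []
    pos = 0
    for tok in small:
        while pos < len(big) and big[pos] != tok:
            pos += 1
        if pos == len(big):
            return None
        out.append(pos)
        pos += 1
    return out


def _one_step_event(segment: tuple[Token, ...], target: tuple[Token, ...],
                    config: SearchConfig) -> Optional[TDRLEvent]:
    """A representative event turning ``segment`` into ``target`` in one
    step, or ``None``.  Exact: an event with in-block losses exists iff the
    target splits as prefix + (subsequence of block+block) + suffix for some
    block — the test below enumerates blocks in the canonical order and uses
    the leftmost loss embedding as representative."""
    if set(segment) - config.free_tokens - set(target):
        return None  # an essential gene would be extinguished
    if len(target) > config.max_segment_length:
        return None
    n = len(segment)
    for i in range(n):
        if segment[:i] != target[:i]:
            break
        for j in range(i, n):
            suffix_len = n - 1 - j
            mid_len = len(target) - i - suffix_len
            length = j - i + 1
            if mid_len < 0 or mid_len > 2 * length:
                continue
            if suffix_len and segment[j + 1:] != target[len(target) - suffix_len:]:
                continue
            block = segment[i:j + 1]
            middle = target[i:len(target) - suffix_len if suffix_len else None]
            kept = _is_subsequence(middle, block + block)
            if kept is None:
                continue
            kept_set = set(kept)
            losses = frozenset(
                ("orig", k) if k < length else ("dup", k - length)
                for k in range(2 * length) if k not in kept_set
            )
            return TDRLEvent(block=(i, j), losses=losses)
    return None


@dataclass
class MinimalScenarios:
    """Result of a minimal-scenario search.

    ``min_events`` is ``None`` when the target is unreachable within the
    configured bound (an explicit result, not an error).  Scenarios are
    deduplicated by their sequence of intermediate states.
    """

    min_events: Optional[int]
    scenarios: list[TDRLScenario] = field(default_factory=list)

    @property
    def state_sequences(self) -> list[list[tuple[Token, ...]]]:
        return [s.intermediate_states() for s in self.scenarios]

    @property
    def reachable(self) -> bool:
        return self.min_events is not None


def search_min_scenarios(from_order: Sequence[Token],
                         to_order: Sequence[Token],
                         config: SearchConfig = SearchConfig()) -> MinimalScenarios:
    """Breadth-first search for the smallest number of TDRL events turning
    ``from_order`` into ``to_order``, with the complete set of minimal
    scenarios (one per distinct intermediate-state sequence)."""
    from_t, to_t = tuple(from_order), tuple(to_order)
    if max(len(from_t), len(to_t)) > config.max_segment_length:
        raise SegmentSizeError(
            f"segment exceeds max_segment_length={config.max_segment_length}"
        )
    missing = set(to_t) - set(from_t)
    if missing:
        raise ValueError(f"target contains genes absent from start: {sorted(missing)}")
    if from_t == to_t:
        return MinimalScenarios(0, [TDRLScenario(from_t)])

    # paths at depth d, deduplicated by state sequence, insertion order =
    # deterministic enumeration order
    paths: dict[tuple, tuple[TDRLEvent, ...]] = {(from_t,): ()}
    for depth in range(1, config.max_events + 1):
        hits = []
        for states, events in paths.items():
            ev = _one_step_event(states[-1], to_t, config)
            if ev is not None:
                hits.append(TDRLScenario(from_t, events + (ev,)))
        if hits:
            return MinimalScenarios(depth, hits)
        if depth == config.max_events:
            break
        nxt: dict[tuple, tuple[TDRLEvent, ...]] = {}
        for states, events in paths.items():
            for ev, res in enumerate_events(states[-1], config):
                key = states + (res,)
                if key not in nxt:
                    nxt[key] = events + (ev,)
        paths = nxt
    return MinimalScenarios(None)


# ---------------------------------------------------------------------------
# Rendering and scenario files
# ---------------------------------------------------------------------------

def copy_labelled(segment: Sequence[Token]) -> list[str]:
    """Attach copy letters a, b, c ... (left to right) to duplicated names."""
    counts: dict[str, int] = {}
    for tok in segment:
        counts[tok] = counts.get(tok, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for tok in segment:
        if counts[tok] > 1:
            k = seen.get(tok, 0)
            seen[tok] = k + 1
            out.append(f"{tok}({chr(ord('a') + k)})")
        else:
            out.append(tok)
    return out


_SHORT = {"tRNA-Thr": "T", "tRNA-Pro": "P", "tRNA-Phe": "F", "rrnS": "12S"}


def render_segment(segment: Sequence[Token], short: bool = True) -> str:
    """Arrow-joined rendering of a segment, e.g. ``CR(a)-F(a)-P-CR(b)-F(b)``."""
    labelled = copy_labelled(segment)
    if short:
        def shorten(lab: str) -> str:
            name, _, rest = lab.partition("(")
            short_name = _SHORT.get(name, name)
            return short_name + ("(" + rest if rest else "")
        labelled = [shorten(lab) for lab in labelled]
    return "-".join(labelled)


def load_scenario(path) -> TDRLScenario:
    """Load a scenario from JSON (see the packaged Fig-6 pathway files)."""
    with open(path) as fh:
        data = json.load(fh)
    events = tuple(
        TDRLEvent(
            block=tuple(ev["block"]),
            losses=frozenset(tuple(x) for x in ev.get("losses", [])),
            segment_losses=frozenset(ev.get("segment_losses", [])),
        )
        for ev in data.get("events", [])
    )
    scen = TDRLScenario(tuple(data["start"]), events, name=data.get("name", ""))
    expected = data.get("expected_end")
    if expected is not None and scen.end_order != tuple(expected):
        raise ScenarioError(
            f"scenario {scen.name or path} does not reach its declared end "
            f"order: got {list(scen.end_order)}, expected {expected}"
        )
    return scen


def packaged_scenario(name: str) -> TDRLScenario:
    """Load one of the shipped scenario files (``fig6_branch_a`` turns the
    ancestral hotspot into the type V order; ``fig6_branch_b`` into type IX)."""
    from importlib import resources
    ref = resources.files("mitorearr.data") / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_scenario(path)
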
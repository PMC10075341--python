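"""Behavioral sequences and first-order Markov transition analysis.

Each visit event yields one behavioral sequence: its bout codes in time
order (after any merge view), with runs of the same code collapsed to a
single state and virtual START/END states bracketing the visit.  Pooling
adjacent state pairs over sequences gives the transition-count matrix of a
first-order Markov chain; row normalisation gives transition probabilities.

The model/results split follows the usual statsmodels idiom:
``MarkovChain(sequences).fit()`` returns a :class:`MarkovChainResults`
holding counts, probabilities, pruning state and exporters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ethogram import INVESTIGATION, default_ethogram
from .events import apply_merge

logger = logging.getLogger(__name__)

START = "START"
END = "END"

#: named analysis presets: merge view + states dropped before collapsing
SEQUENCE_PRESETS = {
    # 3-state diagram: pedal / rubbing / debarking, investigation dropped
    # because it occurs at essentially every transition
    "diagram": dict(view="sequence_view", drop_states=frozenset({INVESTIGATION})),
    # 5-state chain: pedal / investigation / facial / dorsal / debarking
    "full_chain": dict(view="visual_view", drop_states=frozenset()),
}


@dataclass(frozen=True)
class BehaviorSequence:
    """An ordered behavior-state sequence bracketed by START and END."""

    event_id: str
    states: tuple[str, ...]

    def __post_init__(self):
        if self.states[0] != START or self.states[-1] != END:
            raise ValueError("sequence must start with START and end with END")
        inner = self.states[1:-1]
        if any(a == b for a, b in zip(inner, inner[1:])):
            raise ValueError("consecutive duplicate states must be collapsed")

    @property
    def inner(self) -> tuple[str, ...]:
        return self.states[1:-1]


def extract_sequences(events, view=None, drop_states=frozenset(), ethogram=None):
    """Turn visit events into behavioral sequences.

    Parameters
    ----------
    events
        Visit events; if ``view`` is given their bouts are recoded first.
    view
        Optional merge-view name (see :func:`ursamark.ethogram.default_ethogram`).
    drop_states
        Codes removed before duplicate collapsing (e.g. investigation for
        the 3-state diagram).
    """
    if view is not None:
        ethogram = ethogram or default_ethogram()
        events = apply_merge(events, ethogram, view)
    sequences = []
    for ev in events:
        states = [b.behavior for b in ev.bouts if b.behavior not in drop_states]
        collapsed: list[str] = []
        for s in states:
            if not collapsed or collapsed[-1] != s:
                collapsed.append(s)
        if not collapsed:
            logger.warning("event %s has no states after filtering", ev.event_id)
        sequences.append(BehaviorSequence(ev.event_id, (START, *collapsed, END)))
    return sequences


# ---------------------------------------------------------------------------
# transition model


@dataclass(frozen=True)
class TransitionModel:
    """Transition counts/probabilities of a first-order chain.

    ``probs`` rows are count rows normalised to 1; rows with no outgoing
    transitions (END, unseen states) are left at zero and flagged
    absorbing.  Pruning records low-probability edges in ``pruned_edges``
    without renormalising the remaining mass (display semantics).
    """

    states: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray | None = None
    prune_threshold: float | None = None
    pruned_edges: frozenset[tuple[str, str]] = frozenset()

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def absorbing_states(self) -> tuple[str, ...]:
        return tuple(
            s for i, s in enumerate(self.states) if self.counts[i].sum() == 0
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.states, columns=self.states)

    def probs_frame(self) -> pd.DataFrame:
        if self.probs is None:
            raise ValueError("probabilities not estimated yet")
        return pd.DataFrame(self.probs, index=self.states, columns=self.states)

    def prob(self, src: str, dst: str) -> float:
        return float(self.probs[self.index(src), self.index(dst)])


def _state_order(found) -> tuple[str, ...]:
    inner = sorted(set(found) - {START, END})
    return (START, *inner, END)


def count_transitions(sequences, states=None) -> TransitionModel:
    """Pool adjacent state pairs over sequences into a count matrix.

    No transition crosses an event boundary: END of one sequence never
    links to START of the next.
    """
    sequences = list(sequences)
    if states is None:
        found = [s for seq in sequences for s in seq.states]
        states = _state_order(found)
    states = tuple(states)
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=float)
    for seq in sequences:
        for a, b in zip(seq.states, seq.states[1:]):
            counts[idx[a], idx[b]] += 1
    return TransitionModel(states=states, counts=counts)


def estimate_probabilities(model: TransitionModel) -> TransitionModel:
    """Row-normalise the count matrix into transition probabilities."""
    totals = model.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, model.counts / np.where(totals == 0, 1, totals), 0.0)
    return replace(model, probs=probs)


def prune(model: TransitionModel, threshold: float) -> TransitionModel:
    """Mark edges with probability strictly below ``threshold`` as pruned.

    An edge at exactly the threshold is retained.  The probability matrix
    itself is untouched (no renormalisation): pruning only affects what
    the diagram exporters draw.
    """
    if model.probs is None:
        raise ValueError("estimate probabilities before pruning")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    pruned = frozenset(
        (model.states[i], model.states[j])
        for i in range(len(model.states))
        for j in range(len(model.states))
        if model.counts[i, j] > 0 and model.probs[i, j] < threshold
    )
    return replace(model, prune_threshold=threshold, pruned_edges=pruned)


def entry_exit_distribution(model: TransitionModel):
    """Distributions of first behaviors (START row) and last (END column).

    Returns (entry, exit) Series sorted descending by probability.
    """
    if model.probs is None:
        raise ValueError("estimate probabilities before reading entry/exit")
    i_start, i_end = model.index(START), model.index(END)
    entry = pd.Series(model.probs[i_start], index=model.states).drop([START, END])
    entry = entry[entry > 0].sort_values(ascending=False)

    end_counts = model.counts[:, i_end]
    total_exits = end_counts.sum()
    if total_exits == 0:
        warnings.warn("no sequence reaches END; exit table is empty", stacklevel=2)
        exit_dist = pd.Series(dtype=float)
    else:
        exit_dist = pd.Series(end_counts / total_exits, index=model.states).drop(
            [START, END]
        )
        exit_dist = exit_dist[exit_dist > 0].sort_values(ascending=False)
    return entry, exit_dist


def export_dot(model: TransitionModel, labels: dict[str, str] | None = None) -> str:
    """Render unpruned transitions as deterministic Graphviz DOT text.

    Edges are labelled with 2-decimal probabilities; nodes and edges are
    emitted in lexicographic order so identical models yield byte-identical
    output.
    """
    if model.probs is None:
        raise ValueError("estimate probabilities before exporting")
    labels = labels or {}
    lines = ["digraph behavior_sequence {", "  rankdir=LR;"]
    for s in sorted(model.states):
        shape = "plaintext" if s in (START, END) else "ellipse"
        lines.append(f'  "{s}" [label="{labels.get(s, s)}", shape={shape}];')
    edges = []
    for i, a in enumerate(model.states):
        for j, b in enumerate(model.states):
            if model.counts[i, j] > 0 and (a, b) not in model.pruned_edges:
                edges.append((a, b, model.probs[i, j]))
    for a, b, p in sorted(edges):
        lines.append(f'  "{a}" -> "{b}" [label="{p:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence-level summaries


def share_followed_by(model: TransitionModel, src: str, targets) -> float:
    """Of the transitions leaving ``src``, the fraction going to ``targets``."""
    i = model.index(src)
    total = model.counts[i].sum()
    if total == 0:
        return float("nan")
    hit = sum(model.counts[i, model.index(t)] for t in targets if t in model.states)
    return hit / total


def share_preceded_by(sequences, target: str, predecessors) -> float:
    """Fraction of sequences containing ``target`` in which some state in
    ``predecessors`` occurs before the first ``target``."""
    preds = set(predecessors)
    containing = [seq for seq in sequences if target in seq.states]
    if not containing:
        return float("nan")
    ok = 0
    for seq in containing:
        first = seq.states.index(target)
        if preds & set(seq.states[:first]):
            ok += 1
    return ok / len(containing)


# ---------------------------------------------------------------------------
# model/results facade


class MarkovChain:
    """First-order Markov chain over behavioral sequences.

    Parameters
    ----------
    sequences
        :class:`BehaviorSequence` objects (see :func:`extract_sequences`).
    states
        Optional explicit state order; inferred (START, sorted inner
        states, END) when omitted.
    """

    def __init__(self, sequences, states=None):
        self.sequences = list(sequences)
        self.states = states

    @classmethod
    def from_events(cls, events, preset: str = "diagram", ethogram=None):
        """Build directly from visit events using a named preset."""
        spec = SEQUENCE_PRESETS[preset]
        seqs = extract_sequences(
            events, view=spec["view"], drop_states=spec["drop_states"], ethogram=ethogram
        )
        return cls(seqs)

    def fit(self, prune_threshold: float | None = None) -> "MarkovChainResults":
        model = estimate_probabilities(count_transitions(self.sequences, self.states))
        if prune_threshold is not None:
            model = prune(model, prune_threshold)
        return MarkovChainResults(self, model)


@dataclass
class MarkovChainResults:
    """Fitted transition matrix with pruning, entry/exit and exporters."""

    model: MarkovChain
    transition_model: TransitionModel = field(repr=False)

    @property
    def states(self):
        return self.transition_model.states

    @property
    def counts(self) -> pd.DataFrame:
        return self.transition_model.counts_frame()

    @property
    def probs(self) -> pd.DataFrame:
        return self.transition_model.probs_frame()

    @property
    def pruned_edges(self):
        return self.transition_model.pruned_edges

    def prune(self, threshold: float) -> "MarkovChainResults":
        return MarkovChainResults(self.model, prune(self.transition_model, threshold))

    def entry_exit(self):
        return entry_exit_distribution(self.transition_model)

    def to_dot(self, labels=None) -> str:
        return export_dot(self.transition_model, labels)

    @property
    def n_sequences(self) -> int:
        return len(self.model.sequences)

    @property
    def n_transitions(self) -> int:
        return int(self.transition_model.counts.sum())

    def summary(self) -> str:
        tm = self.transition_model
        lines = [
            "First-order Markov chain over behavioral sequences",
            f"  sequences: {self.n_sequences}    transitions: {self.n_transitions}",
            f"  states: {', '.join(tm.states)}",
        ]
        if tm.prune_threshold is not None:
            shown = ", ".join(f"{a}->{b}" for a, b in sorted(tm.pruned_edges)) or "none"
            lines.append(f"  pruned (< {tm.prune_threshold}): {shown}")
        lines.append("")
        lines.append(self.probs.round(3).to_string())
        return "\n".join(lines)


__all__ = [
    "START",
    "END",
    "SEQUENCE_PRESETS",
    "BehaviorSequence",
    "TransitionModel",
    "extract_sequences",
    "count_transitions",
    "estimate_probabilities",
    "prune",
    "entry_exit_distribution",
    "export_dot",
    "share_followed_by",
    "share_preceded_by",
    "MarkovChain",
    "MarkovChainResults",
]
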
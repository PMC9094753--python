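"""NGS enrichment analysis of phage-selected qtRNA libraries.

Reads from a selected library are matched by exact string search for the
constant flanks bounding the randomized window; the randomized bases in
between form the member key.  Per-member log10 fold enrichment compares
post-selection to pre-selection frequencies with a Laplace pseudocount,
and per-position nucleotide marginals summarize positional preferences
(e.g. the prominent A37 preference seen in loop-side selections).
Phage-titer fold change gives the selection-level readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from Bio.Seq import Seq

from .design import DNA_BASES, DegenerateLibrary


class Phase(str, Enum):
    PRE = "PRE"
    POST = "POST"


class LibraryClass(str, Enum):
    NO_PRESSURE = "NO_PRESSURE"
    SINGLE_DOMINANT = "SINGLE_DOMINANT"
    POSITIONAL_PREFERENCE = "POSITIONAL_PREFERENCE"


@dataclass
class LibraryCounts:
    """Member counts extracted from one phase's read set."""

    library: DegenerateLibrary
    phase: Phase
    counts: dict[str, int]
    n_reads_total: int
    n_discarded: int

    @property
    def n_counted(self) -> int:
        return self.n_reads_total - self.n_discarded

    def frequencies(self) -> dict[str, float]:
        total = self.n_counted
        return {k: v / total for k, v in self.counts.items()} if total else {}


@dataclass
class EnrichmentResult:
    """Per-member log10 fold enrichment plus positional summaries."""

    enrichment: dict[str, float]
    marginals_pre: list[dict[str, float]]
    marginals_post: list[dict[str, float]]
    position_labels: tuple[str, ...]
    library_class: LibraryClass
    top_member: str
    runner_up_gap: float          # top minus runner-up enrichment (log10)


@dataclass
class TiterRecord:
    """Pre/post phage titers for one selection."""

    selection: str
    pre_pfu_ml: float
    post_pfu_ml: float

    @property
    def log_fold_change(self) -> float:
        return titer_log_fold_change(self.pre_pfu_ml, self.post_pfu_ml)


def _extract_window(read: str, library: DegenerateLibrary) -> str | None:
    """Member key from one read, or None when the read must be discarded."""
    i = read.find(library.flank_5)
    if i < 0:
        return None
    start = i + len(library.flank_5)
    end = start + library.window_length
    if read[end : end + len(library.flank_3)] != library.flank_3:
        return None
    window = read[start:end]
    if len(window) != library.window_length:
        return None
    key = "".join(window[o] for o in library.randomized_offsets)
    if any(b not in DNA_BASES for b in key):
        return None
    return key if key in library.members else None


def count_library_members(
    reads: Iterable[str],
    library: DegenerateLibrary,
    phase: Phase | str = Phase.PRE,
    search_reverse_complement: bool = True,
) -> LibraryCounts:
    """Tally library members across a read set by exact flank matching.

    Reads whose flanks do not match, whose window has the wrong length, or
    whose randomized bases fall outside ACGT are discarded (and counted as
    such).  By default the reverse complement of a read is also searched,
    so counting is orientation-agnostic.
    """
    if not library.flank_5 or not library.flank_3:
        raise ValueError("library does not define both flanks; cannot match reads")
    counts = {k: 0 for k in library.members}
    total = 0
    discarded = 0
    for read in reads:
        read = str(read).upper()
        total += 1
        key = _extract_window(read, library)
        if key is None and search_reverse_complement:
            key = _extract_window(str(Seq(read).reverse_complement()), library)
        if key is None:
            discarded += 1
        else:
            counts[key] += 1
    return LibraryCounts(
        library=library,
        phase=Phase(phase),
        counts=counts,
        n_reads_total=total,
        n_discarded=discarded,
    )


def _marginals(counts: Mapping[str, int], n_positions: int
               ) -> list[dict[str, float]]:
    total = sum(counts.values())
    out = []
    for pos in range(n_positions):
        freqs = {b: 0.0 for b in DNA_BASES}
        if total:
            for key, c in counts.items():
                freqs[key[pos]] += c
            freqs = {b: v / total for b, v in freqs.items()}
        out.append(freqs)
    return out


def classify_library(
    enrichment: Mapping[str, float],
    marginals_post: Sequence[Mapping[str, float]],
    dominant_enrichment: float = 1.0,
    gap_threshold: float = 1.0,
    pressure_threshold: float = 0.5,
    marginal_dominance: float = 0.75,
) -> LibraryClass:
    """Classify a selected library from its enrichment profile.

    SINGLE_DOMINANT: the top member is enriched >= *dominant_enrichment*
    log10 and leads the runner-up by >= *gap_threshold* log10.
    NO_PRESSURE: no member moves more than *pressure_threshold* log10 in
    either direction.  Otherwise POSITIONAL_PREFERENCE when some position
    has a post-selection base at frequency >= *marginal_dominance*, else
    NO_PRESSURE.  Thresholds are configurable analysis choices.
    """
    vals = sorted(enrichment.values(), reverse=True)
    if len(vals) >= 2 and vals[0] >= dominant_enrichment and \
            vals[0] - vals[1] >= gap_threshold:
        return LibraryClass.SINGLE_DOMINANT
    if max(abs(v) for v in vals) < pressure_threshold:
        return LibraryClass.NO_PRESSURE
    for freqs in marginals_post:
        if max(freqs.values()) >= marginal_dominance:
            return LibraryClass.POSITIONAL_PREFERENCE
    return LibraryClass.NO_PRESSURE


def log_fold_enrichment(
    pre: LibraryCounts,
    post: LibraryCounts,
    pseudocount: float = 1.0,
) -> EnrichmentResult:
    """Per-member log10 fold enrichment of post- over pre-selection frequency.

    Frequencies use Laplace smoothing: (c + psi) / (N + psi * K) with K
    members, which keeps zero-count members finite and makes the result
    exactly antisymmetric under swapping pre and post.
    """
    if pre.library is not post.library and pre.library.members.keys() != \
            post.library.members.keys():
        raise ValueError("pre and post counts come from different libraries")
    if pre.n_counted == 0 or post.n_counted == 0:
        raise ValueError("zero usable reads in one phase; cannot compute enrichment")
    keys = sorted(pre.library.members)
    k = len(keys)
    n_pre = pre.n_counted + pseudocount * k
    n_post = post.n_counted + pseudocount * k
    enr = {
        key: math.log10(
            ((post.counts.get(key, 0) + pseudocount) / n_post)
            / ((pre.counts.get(key, 0) + pseudocount) / n_pre)
        )
        for key in keys
    }
    n_positions = len(pre.library.randomized_offsets)
    m_pre = _marginals(pre.counts, n_positions)
    m_post = _marginals(post.counts, n_positions)
    ranked = sorted(enr, key=enr.get, reverse=True)
    top = ranked[0]
    gap = enr[top] - enr[ranked[1]] if len(ranked) > 1 else math.inf
    return EnrichmentResult(
        enrichment=enr,
        marginals_pre=m_pre,
        marginals_post=m_post,
        position_labels=pre.library.position_labels,
        library_class=classify_library(enr, m_post),
        top_member=top,
        runner_up_gap=gap,
    )


def titer_log_fold_change(pre_titer: float, post_titer: float) -> float:
    """log10 of post- over pre-selection phage titer (pfu/mL)."""
    if pre_titer <= 0 or post_titer <= 0:
        raise ValueError("titers must be positive for a defined log fold change")
    return math.log10(post_titer / pre_titer)


def rank_selections(
    records: Sequence[TiterRecord], fold_threshold: float = 10.0
) -> list[tuple[TiterRecord, float, bool]]:
    """Sort selections by titer log fold change, flagging those that pass.

    A selection passes when post/pre exceeds *fold_threshold* strictly
    ("over 10-fold"); returns (record, log10 fold change, passed) tuples
    in descending order.
    """
    ranked = sorted(records, key=lambda r: r.log_fold_change, reverse=True)
    return [
        (r, r.log_fold_change, r.post_pfu_ml / r.pre_pfu_ml > fold_threshold)
        for r in ranked
    ]


def positional_preference(
    result: EnrichmentResult, dominance_threshold: float = 0.75
) -> dict[str, str]:
    """Label each randomized position with its dominant post-selection base.

    A position gets its base letter when that base's post-selection
    marginal frequency is >= *dominance_threshold*, otherwise "mixed".
    """
    labels = {}
    for label, freqs in zip(result.position_labels, result.marginals_post):
        best = max(freqs, key=freqs.get)
        labels[label] = best if freqs[best] >= dominance_threshold else "mixed"
    return labels
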
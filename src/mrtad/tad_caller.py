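"""Contiguity-constrained Louvain TAD calling with consensus boundaries.

The heuristic optimizes the resolution-parameterized modularity Q under
the constraint that every domain is a contiguous run of bins.  One trial:

1. start from singletons; repeatedly sweep the bins in a fresh random
   order, letting each segment-endpoint bin adopt the label of its left or
   right neighboring segment (or stay) — whichever strictly increases Q
   most — until a full sweep makes no move;
2. lock each segment into a super-bin and sweep the super-bins the same
   way (adjacent merges only) until no merge improves Q, then regroup the
   locked segments by an exact chain dynamic program (still merges only,
   so Q is monotone);
3. alternate the two phases until a full cycle changes nothing.

Because the update order is random, repeated trials differ; the boundary
score of a border is the fraction of trials in which it separates two
domains, and borders scoring at least the cutoff (default 0.9 with 10
trials, i.e. at least 9 of 10) become consensus boundaries delimiting the
reported TADs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_map import ContactMap
from .modularity import PartitionState, ResolutionConfig, pair_score_matrix
from .null_model import (
    NullModel,
    estimate_distance_decay,
    expected_map,
    solve_effective_coverage,
)

__all__ = [
    "UNASSIGNED",
    "Partition",
    "BoundaryScoreTrack",
    "TADSet",
    "CallerConfig",
    "run_louvain_trial",
    "boundary_scores",
    "consensus_tads",
    "call_tads",
    "sweep_resolutions",
]

#: sentinel label for bins not assigned to any domain
UNASSIGNED = -1


@dataclass
class Partition:
    """Assignment of bins to contiguous domains (sentinel -1 = unassigned)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def is_contiguous(self) -> bool:
        """True iff every label's bin set is one contiguous run."""
        seen: set[int] = set()
        prev = None
        for lab in self.labels:
            if lab != prev:
                if lab in seen:
                    return False
                if lab != UNASSIGNED:
                    seen.add(int(lab))
                prev = lab
        return True

    def boundaries(self) -> np.ndarray:
        """Internal borders ``k`` (1..n-1) where the label changes."""
        return np.flatnonzero(self.labels[1:] != self.labels[:-1]) + 1


@dataclass
class BoundaryScoreTrack:
    """Per-border fraction of trials calling the border a boundary.

    ``scores`` has length ``n + 1``; border ``k`` sits between bins ``k-1``
    and ``k``; the chromosome ends (borders 0 and n) score 1 by convention.
    """

    scores: np.ndarray
    n_trials: int
    chrom: str | None = None
    bin_size: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class TADSet:
    """Consensus domains as sorted, non-overlapping half-open bin intervals."""

    intervals: list[tuple[int, int]]
    chrom: str
    bin_size: int

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("TAD intervals overlap or are unsorted")
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)

    def sizes_bp(self) -> np.ndarray:
        return np.array([(e - s) * self.bin_size for s, e in self.intervals])

    def to_partition(self, n: int) -> Partition:
        labels = np.full(n, UNASSIGNED, dtype=int)
        for k, (s, e) in enumerate(self.intervals):
            labels[s:e] = k
        return Partition(labels)


@dataclass
class CallerConfig:
    """Tunable parameters of the consensus caller.

    ``n_trials`` stochastic Louvain runs are scored; borders with score
    ``>= cutoff`` become consensus boundaries.  ``max_sweeps`` and
    ``max_levels`` are safety caps that normal runs never reach.
    """

    gamma: float = 1.0
    n_trials: int = 10
    cutoff: float = 0.9
    seed: int = 0
    max_levels: int = 100
    max_sweeps: int = 10_000
    include_diagonal: bool = True
    decay_span: float = 0.01
    solver_tol: float = 1e-6
    solver_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must lie in (0, 1]")


def _bin_sweeps(state: PartitionState, rng: np.random.Generator, max_sweeps: int) -> bool:
    """Phase 1: endpoint-bin label updates until a full sweep makes no move."""
    n = state.n
    any_move = False
    for _ in range(max_sweeps):
        moved = False
        for b in rng.permutation(n):
            s, e = state.segment_of(b)
            dql = state.delta_q_move(b, "left") if (b == s and s > 0) else -np.inf
            dqr = state.delta_q_move(b, "right") if (b == e - 1 and e < n) else -np.inf
            # ties broken toward the lower-indexed (left) side
            if dql >= dqr and dql > 0:
                state.apply_move(b, "left")
                moved = True
            elif dqr > 0:
                state.apply_move(b, "right")
                moved = True
        if not moved:
            break
        any_move = True
    return any_move


def _merge_sweeps(state: PartitionState, rng: np.random.Generator, max_sweeps: int) -> bool:
    """Phase 2: segments act as locked super-bins; adjacent merges only."""
    any_merge = False
    for _ in range(max_sweeps):
        merged = False
        order = rng.permutation(list(state.segs.keys()))
        for lab in order:
            lab = int(lab)
            if lab not in state.segs:
                continue  # already absorbed earlier in this sweep
            s, e = state.segs[lab]
            left = int(state.labels[s - 1]) if s > 0 else None
            right = int(state.labels[e]) if e < state.n else None
            gl = state.merge_gain(left, lab) if left is not None else -np.inf
            gr = state.merge_gain(lab, right) if right is not None else -np.inf
            if gl >= gr and gl > 0:
                state.apply_merge(left, lab)
                merged = True
            elif gr > 0:
                state.apply_merge(lab, right)
                merged = True
        if not merged:
            break
        any_merge = True
    return any_merge


def _louvain(state: PartitionState, rng: np.random.Generator, config: CallerConfig) -> None:
    for _ in range(config.max_levels):
        moved = _bin_sweeps(state, rng, config.max_sweeps)
        merged = _merge_sweeps(state, rng, config.max_sweeps)
        # pairwise dynamics can stall where a small noise-locked segment
        # blocks profitable larger-scale merges; regroup the locked
        # segments optimally (merges only, Q monotone) before the next level
        regrouped = state.regroup_segments()
        if not (moved or merged or regrouped):
            break


def run_louvain_trial(
    cmap: ContactMap,
    model: NullModel,
    config: CallerConfig,
    rng: np.random.Generator,
    *,
    _state: PartitionState | None = None,
) -> tuple[Partition, float]:
    """One stochastic contiguity-constrained Louvain run.

    Returns the contiguous partition and the Q it achieved.  ``_state``
    lets :func:`call_tads` share the precomputed score arrays between
    trials; external callers can ignore it.
    """
    if cmap.n < 2:
        raise ValueError("need at least 2 bins")
    if _state is None:
        rcfg = ResolutionConfig(config.gamma, config.include_diagonal)
        q = pair_score_matrix(cmap, expected_map(model), rcfg)
        state = PartitionState(q)
    else:
        state = _state
        state.reset()
    _louvain(state, rng, config)
    return Partition(state.to_labels()), state.total_q()


def boundary_scores(
    trials: list[Partition],
    chrom: str | None = None,
    bin_size: int | None = None,
) -> BoundaryScoreTrack:
    """Fraction of trials in which each of the n+1 borders is a boundary."""
    if not trials:
        raise ValueError("need at least one trial")
    n = trials[0].n
    if any(t.n != n for t in trials):
        raise ValueError("trials have mixed lengths")
    scores = np.zeros(n + 1)
    scores[0] = scores[n] = 1.0
    labels = np.stack([t.labels for t in trials])
    scores[1:n] = (labels[:, 1:] != labels[:, :-1]).mean(axis=0)
    return BoundaryScoreTrack(scores=scores, n_trials=len(trials), chrom=chrom, bin_size=bin_size)


def consensus_tads(track: BoundaryScoreTrack, cmap: ContactMap, cutoff: float = 0.9) -> TADSet:
    """Threshold the boundary track and emit the domains between boundaries.

    A border is a consensus boundary when its score is at least ``cutoff``
    (0.9 with 10 trials means called in at least 9 of 10).  Runs made up
    entirely of zero-coverage bins are dropped, and zero-coverage bins at a
    run's edges are trimmed (left unassigned).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    n = cmap.n
    if track.scores.shape[0] != n + 1:
        raise ValueError("track length does not match the map")
    eps = 1e-12  # guards float representation of k / n_trials
    cuts = [0] + [k for k in range(1, n) if track.scores[k] >= cutoff - eps] + [n]
    cov = cmap.coverage
    intervals: list[tuple[int, int]] = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        while s < e and cov[s] == 0:
            s += 1
        while e > s and cov[e - 1] == 0:
            e -= 1
        if e > s:
            intervals.append((s, e))
    return TADSet(intervals=intervals, chrom=cmap.chrom, bin_size=cmap.bin_size)


def _build_state(cmap: ContactMap, model: NullModel, config: CallerConfig) -> PartitionState:
    rcfg = ResolutionConfig(config.gamma, config.include_diagonal)
    q = pair_score_matrix(cmap, expected_map(model), rcfg)
    return PartitionState(q)


def call_tads(
    cmap: ContactMap,
    config: CallerConfig | None = None,
    *,
    model: NullModel | None = None,
) -> tuple[TADSet, BoundaryScoreTrack, list[float]]:
    """Full pipeline: null model, stochastic trials, scoring, consensus.

    Child RNG seeds are spawned deterministically from ``config.seed``, so
    the result is bit-reproducible.  A pre-solved ``model`` may be supplied
    (e.g. by :func:`sweep_resolutions`) to skip re-estimation.
    """
    config = config or CallerConfig()
    if model is None:
        decay = estimate_distance_decay(cmap, config.decay_span)
        model = solve_effective_coverage(
            cmap, decay, tol=config.solver_tol, max_iter=config.solver_max_iter
        )
    if not model.converged:
        warnings.warn(
            f"null model not converged (residual {model.residual:.3e}); "
            "proceeding with best iterate",
            RuntimeWarning,
        )
    state = _build_state(cmap, model, config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    trials: list[Partition] = []
    qs: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        part, q = run_louvain_trial(cmap, model, config, rng, _state=state)
        trials.append(part)
        qs.append(q)
    track = boundary_scores(trials, chrom=cmap.chrom, bin_size=cmap.bin_size)
    tads = consensus_tads(track, cmap, config.cutoff)
    return tads, track, qs


def sweep_resolutions(
    cmap: ContactMap,
    gammas: list[float],
    config: CallerConfig | None = None,
) -> tuple[dict[float, TADSet], pd.DataFrame]:
    """Call TADs at several resolutions, reusing one null model.

    Returns the per-gamma TAD sets and a summary table with columns
    ``gamma``, ``n_tads`` and ``median_size_bp``.
    """
    if not gammas:
        raise ValueError("gamma list is empty")
    if sorted(gammas) != list(gammas):
        raise ValueError("gammas must be sorted ascending")
    config = config or CallerConfig()
    decay = estimate_distance_decay(cmap, config.decay_span)
    model = solve_effective_coverage(
        cmap, decay, tol=config.solver_tol, max_iter=config.solver_max_iter
    )
    results: dict[float, TADSet] = {}
    rows = []
    for g in gammas:
        cfg = CallerConfig(**{**config.__dict__, "gamma": g})
        tads, _, _ = call_tads(cmap, cfg, model=model)
        results[g] = tads
        sizes = tads.sizes_bp()
        rows.append(
            {
                "gamma": g,
                "n_tads": len(tads),
                "median_size_bp": float(np.median(sizes)) if len(sizes) else float("nan"),
            }
        )
    return results, pd.DataFrame(rows)
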
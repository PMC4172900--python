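"""Recursive partitioning and amalgamation of censored cohorts (RECPAM-style).

Grows a binary survival tree: at each node every candidate covariate is
scanned over all admissible binary splits (threshold midpoints for continuous
covariates, level subsets for categoricals), each split scored by the
likelihood-ratio chi-square of a single-indicator Cox model (Breslow ties).
The splitting *variable* is chosen by a permutation test on the covariate's
maximal split statistic — the covariate's values are shuffled among node
members with outcomes fixed — and a node is split only when the winning
permutation p-value passes the gate (alpha). Stopping rules: every leaf keeps
at least ``min_events`` events and ``min_subjects`` subjects, plus a depth cap.

Terminal nodes are then amalgamated into risk classes (optional; with
amalgamation alpha = 1 the leaves are the classes), the class with the lowest
crude event rate becomes the reference, and hazard ratios with Wald 95% CIs
are reported from one Cox fit on class indicators. Class clinical profiles
are compared with Kruskal-Wallis (continuous) and exact Fisher tests
(categorical, full enumeration for small r x c tables).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .survcore import (
    CoxFit,
    Z_95,
    binary_cox_batch,
    class_survival_curves,
    fit_cox,
    incidence_rate,
    risk_set_starts,
)

__all__ = [
    "Stopping",
    "SplitCandidate",
    "Node",
    "RecpamTree",
    "RiskClassTable",
    "candidate_splits",
    "evaluate_split",
    "select_split_variable",
    "grow_tree",
    "amalgamate",
    "risk_class_curves",
    "class_profiles",
    "report_tree",
    "tree_to_dict",
    "fisher_exact_rxc",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12  # statistics closer than this are ties


@dataclass(frozen=True)
class Stopping:
    """Leaf admissibility floor: both children of any split must keep at
    least this many events and subjects."""

    min_events: int = 1
    min_subjects: int = 3


@dataclass
class SplitCandidate:
    """One admissible binary split of a node.

    ``threshold`` is a float for continuous covariates (right child = value >
    threshold) or a frozenset of levels for categoricals (right child = value
    in subset). ``statistic`` is the LR chi-square of the indicator Cox fit.
    """

    covariate: str
    threshold: object
    statistic: float = float("nan")
    hr: float = float("nan")
    ci95_low: float = float("nan")
    ci95_high: float = float("nan")
    left_n: int = 0
    right_n: int = 0
    left_events: int = 0
    right_events: int = 0
    converged: bool = True

    def goes_right(self, value) -> bool:
        if isinstance(self.threshold, frozenset):
            return value in self.threshold
        return value > self.threshold


@dataclass
class Node:
    id: int
    depth: int
    member_ids: list
    n_events: int
    n_nonevents: int
    split: SplitCandidate | None = None
    children: tuple[int, int] | None = None
    permutation_p: float | None = None  # joint gate p compared with alpha
    selection_p: float | None = None  # winning covariate's own permutation p
    selected_covariate: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class RecpamTree:
    endpoint: str
    root_id: int
    nodes: dict[int, Node]
    stopping: Stopping
    permutations: int
    alpha: float
    max_depth: int
    seed: int
    covariates: list[str]

    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    @property
    def leaves(self) -> list[Node]:
        return [self.nodes[i] for i in sorted(self.nodes) if self.nodes[i].is_leaf]


@dataclass
class RiskClassTable:
    """Final amalgamated risk classes, ordered by decreasing hazard ratio.

    ``classes`` columns: class_id, leaf_ids, n, n_events, hr, ci95_low,
    ci95_high, rate_per_100py, median_followup_months. ``assignment`` maps
    each cohort row (by patient_id) to its class.
    """

    classes: pd.DataFrame
    reference_class_id: str
    assignment: pd.Series
    cox: CoxFit


# ---------------------------------------------------------------------------
# Node-level survival scaffolding
# ---------------------------------------------------------------------------


class _NodeSurv:
    """Time-sorted view of a node's outcomes, reused across candidates."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        self.n = times.shape[0]
        self.order = np.argsort(times, kind="stable")
        self.t = times[self.order]
        self.e = events[self.order].astype(bool)
        starts = risk_set_starts(self.t)
        self.starts_e = starts[self.e]
        self.r_total = self.n - self.starts_e  # at-risk size at each event
        self.total_events = int(self.e.sum())

    def batch(self, X: np.ndarray, presorted: bool = False):
        """LR statistics etc. for indicator columns X (n x C).

        Columns are in member order unless ``presorted`` (already in the
        node's ascending-time order). Arithmetic runs in X's float dtype:
        float64 for observed scans, float32 for permutation nulls (at-risk
        counts are small integers, exact in either).
        """
        Xs = X if presorted else X[self.order]
        suff = np.zeros((self.n + 1, Xs.shape[1]), dtype=Xs.dtype)
        suff[:-1] = np.cumsum(Xs[::-1], axis=0)[::-1]
        n1 = suff[self.starts_e]
        n0 = self.r_total[:, None].astype(Xs.dtype) - n1
        s1 = Xs[self.e].sum(axis=0)
        beta, lr, se, conv = binary_cox_batch(n1, n0, s1)
        return beta, lr, se, conv, s1, Xs.sum(axis=0)


def _thresholds_and_matrix(values: np.ndarray, categorical: bool):
    """All binary splits of a covariate: (list of thresholds/subsets,
    indicator matrix n x m with column j = right-child membership)."""
    if categorical:
        levels = sorted(pd.unique(values), key=str)
        if len(levels) < 2:
            return [], np.zeros((values.shape[0], 0))
        # one representative per complement pair: subsets not containing levels[0]
        subsets = []
        for r in range(1, len(levels)):
            for combo in itertools.combinations(levels[1:], r):
                subsets.append(frozenset(combo))
        X = np.column_stack([np.isin(values, list(s)).astype(float) for s in subsets])
        return subsets, X
    v = values.astype(float)
    u = np.unique(v)
    if u.size < 2:
        return [], np.zeros((v.shape[0], 0))
    thr = (u[:-1] + u[1:]) / 2.0
    X = (v[:, None] > thr[None, :]).astype(float)
    return list(map(float, thr)), X


def _admissible_mask(count1, s1, n, total_events, stopping: Stopping):
    ms, me = stopping.min_subjects, stopping.min_events
    count1 = np.asarray(count1, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    return (
        (count1 >= ms)
        & (n - count1 >= ms)
        & (s1 >= me)
        & (total_events - s1 >= me)
    )


# ---------------------------------------------------------------------------
# Spec operations
# ---------------------------------------------------------------------------


def candidate_splits(
    values,
    events,
    stopping: Stopping = Stopping(),
    covariate: str = "",
    categorical: bool = False,
) -> list[SplitCandidate]:
    """Enumerate admissible binary splits of one covariate within a node.

    Continuous: midpoints between consecutive distinct sorted values.
    Categorical: all nonempty proper level subsets (complements deduplicated).
    A split is admissible when both children keep >= min_subjects subjects and
    >= min_events events. An empty list is a valid return.
    """
    v = np.asarray(values)
    e = np.asarray(events, dtype=int)
    thresholds, X = _thresholds_and_matrix(v, categorical)
    if not thresholds:
        return []
    count1 = X.sum(axis=0)
    s1 = X[e == 1].sum(axis=0)
    n, total_events = v.shape[0], int(e.sum())
    mask = _admissible_mask(count1, s1, n, total_events, stopping)
    out = []
    for j, thr in enumerate(thresholds):
        if mask[j]:
            out.append(
                SplitCandidate(
                    covariate=covariate,
                    threshold=thr,
                    left_n=int(n - count1[j]),
                    right_n=int(count1[j]),
                    left_events=int(total_events - s1[j]),
                    right_events=int(s1[j]),
                )
            )
    return out


def evaluate_split(times, events, values, candidate: SplitCandidate) -> SplitCandidate:
    """Score one candidate: LR chi-square 2*(logPL(beta) - logPL(0)) of the
    Cox model on the right-child indicator; HR and Wald CI retained for
    reporting. A non-converged (separated) fit is flagged so the caller can
    discard the candidate."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    v = np.asarray(values)
    ns = _NodeSurv(t, e)
    if isinstance(candidate.threshold, frozenset):
        x = np.isin(v, list(candidate.threshold)).astype(float)
    else:
        x = (v.astype(float) > candidate.threshold).astype(float)
    beta, lr, se, conv, s1, count1 = ns.batch(x[:, None])
    candidate.statistic = float(lr[0])
    candidate.hr = float(np.exp(beta[0]))
    candidate.ci95_low = float(np.exp(beta[0] - Z_95 * se[0]))
    candidate.ci95_high = float(np.exp(beta[0] + Z_95 * se[0]))
    candidate.converged = bool(conv[0])
    candidate.right_n = int(count1[0])
    candidate.left_n = int(ns.n - count1[0])
    candidate.right_events = int(s1[0])
    candidate.left_events = int(ns.total_events - s1[0])
    if not candidate.converged:
        logger.info(
            "split %s @ %s discarded: Cox fit did not converge (risk separation)",
            candidate.covariate,
            candidate.threshold,
        )
    return candidate


def _scan_covariate(
    values: np.ndarray,
    ns: _NodeSurv,
    stopping: Stopping,
    categorical: bool,
    permutations: list[np.ndarray],
    covariate: str,
):
    """Best admissible split of one covariate plus its permutation null.

    Returns (T_max_observed, best SplitCandidate, t_perm) where t_perm[b] is
    the covariate's maximal split statistic under the b-th permutation of its
    values among node members (outcomes fixed; -inf when no admissible,
    converged split exists under that permutation), or None when the observed
    covariate has no admissible, converged split. The same convergence filter
    applies on both sides of the comparison.
    """
    thresholds, X = _thresholds_and_matrix(values, categorical)
    if not thresholds:
        return None
    m = len(thresholds)
    n = ns.n
    beta, lr, se, conv, s1, count1 = ns.batch(X)
    mask = _admissible_mask(count1, s1, n, ns.total_events, stopping) & conv
    if not mask.any():
        return None
    scored = np.where(mask, lr, -np.inf)
    t_obs = float(scored.max())
    # ties to within 1e-12 broken by the smaller threshold (subsets: sort key)
    tied = np.flatnonzero(scored >= t_obs - _TIE_TOL)
    if categorical:
        best_j = min(tied, key=lambda j: sorted(map(str, thresholds[j])))
    else:
        best_j = min(tied, key=lambda j: thresholds[j])
    best = SplitCandidate(
        covariate=covariate,
        threshold=thresholds[best_j],
        statistic=float(lr[best_j]),
        hr=float(np.exp(beta[best_j])),
        ci95_low=float(np.exp(beta[best_j] - Z_95 * se[best_j])),
        ci95_high=float(np.exp(beta[best_j] + Z_95 * se[best_j])),
        left_n=int(n - count1[best_j]),
        right_n=int(count1[best_j]),
        left_events=int(ns.total_events - s1[best_j]),
        right_events=int(s1[best_j]),
        converged=True,
    )

    B = len(permutations)
    t_perm = np.full(B, -np.inf)
    # column sums (child sizes) are permutation-invariant; only the event
    # side-counts move, so the subject-count part of admissibility is fixed
    size_ok = (count1 >= stopping.min_subjects) & (n - count1 >= stopping.min_subjects)
    Xt = X[ns.order].astype(np.float32)  # time-sorted once; null runs in float32
    chunk = max(1, int(4_000_000 // max(n * m, 1)))
    done = 0
    while done < B:
        k = min(chunk, B - done)
        cols = np.empty((n, k * m), dtype=np.float32)
        for i in range(k):
            cols[:, i * m : (i + 1) * m] = Xt[permutations[done + i]]
        _, lr_p, _, conv_p, s1_p, _ = ns.batch(cols, presorted=True)
        ev_ok = (s1_p >= stopping.min_events) & (
            ns.total_events - s1_p >= stopping.min_events
        )
        ok = ev_ok & conv_p & np.tile(size_ok, k)
        scored_p = np.where(ok, lr_p.astype(np.float64), -np.inf).reshape(k, m)
        t_perm[done : done + k] = scored_p.max(axis=1)
        done += k
    return t_obs, best, t_perm


@dataclass(frozen=True)
class SplitSelection:
    """Winner of a node's split-variable competition.

    ``permutation_p`` is the winning covariate's own permutation p-value
    (selection ranking); ``gate_p`` is the joint permutation p-value of the
    node's best statistic against the null of max-over-covariates permuted
    T_max — the quantity the split gate compares to alpha, which keeps the
    node-wise false-split probability at alpha regardless of how many
    covariates compete.
    """

    covariate: str
    candidate: SplitCandidate
    permutation_p: float
    gate_p: float

    def __iter__(self):  # (covariate, candidate, permutation_p) unpacking
        return iter((self.covariate, self.candidate, self.permutation_p))


def select_split_variable(
    records: pd.DataFrame,
    covariates,
    stopping: Stopping = Stopping(),
    n_permutations: int = 199,
    seed: int | np.random.Generator = 0,
    categorical: set | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> SplitSelection | None:
    """Choose the splitting variable for a node by permutation p-value.

    For each covariate, T_max is the maximal LR statistic over its admissible
    splits; its p-value is (1 + #{permuted T_max >= observed}) / (1 + B),
    permuting the covariate's values among node members with outcomes fixed.
    The winner has the smallest p, ties broken by larger observed T_max, then
    by covariate name. One shared set of B member permutations drives every
    fully-observed covariate, so the joint null (max over covariates per
    permutation) is also available; ``gate_p`` is the add-one p-value of the
    best observed statistic against that joint null. Returns None when no
    covariate has an admissible split. Patients missing a covariate stay in
    the node but are excluded from that covariate's evaluation (which then
    draws its own permutations over its observed subset).
    """
    categorical = categorical or set()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_all = records[time_col].to_numpy(dtype=float)
    e_all = records[event_col].to_numpy(dtype=int)
    n = len(records)
    B = int(n_permutations)
    shared_perms = [rng.permutation(n) for _ in range(B)]
    results = []
    for cov in covariates:
        col = records[cov]
        present = col.notna().to_numpy()
        if not present.all():
            logger.info(
                "covariate %s: %d member(s) missing, evaluated on the rest",
                cov,
                int((~present).sum()),
            )
        if present.sum() < 2 * stopping.min_subjects:
            continue
        vals = col.to_numpy()[present]
        ns = _NodeSurv(t_all[present], e_all[present])
        if ns.total_events < 2 * stopping.min_events:
            continue
        if present.all():
            perms = shared_perms
        else:
            perms = [rng.permutation(int(present.sum())) for _ in range(B)]
        res = _scan_covariate(vals, ns, stopping, cov in categorical, perms, cov)
        if res is not None:
            t_obs, cand, t_perm = res
            p = (1.0 + int((t_perm >= t_obs - _TIE_TOL).sum())) / (1.0 + B)
            results.append((p, -t_obs, str(cov), cand, t_perm))
    if not results:
        return None
    results.sort(key=lambda r: r[:3])
    p, neg_t, name, cand, _ = results[0]
    t_best = max(-r[1] for r in results)
    joint_null = np.max(np.stack([r[4] for r in results]), axis=0)
    gate_p = (1.0 + int((joint_null >= t_best - _TIE_TOL).sum())) / (1.0 + B)
    return SplitSelection(cand.covariate, cand, p, gate_p)


# ---------------------------------------------------------------------------
# Tree growing
# ---------------------------------------------------------------------------


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    ep = endpoint.lower()
    if ep not in ("os", "pfs"):
        raise ValueError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    return f"{ep}_time", f"{ep}_event"


def grow_tree(
    cohort: pd.DataFrame,
    endpoint: str,
    covariates,
    stopping: Stopping = Stopping(),
    n_permutations: int = 199,
    alpha: float = 0.05,
    max_depth: int = 5,
    seed: int = 0,
    categorical: set | None = None,
) -> RecpamTree:
    """Grow the survival tree on one endpoint.

    A node is split only when the winning covariate's permutation p-value is
    <= alpha and both children are admissible; otherwise it becomes a leaf.
    Per-node RNG substreams are derived from (seed, node id) so the tree is a
    pure function of (cohort, settings, seed). Node ids follow heap order
    (root 1, children 2i and 2i+1). Patients with a missing value on the
    chosen split covariate follow the larger child.
    """
    covariates = list(covariates)
    time_col, event_col = _endpoint_cols(endpoint)
    times = cohort[time_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy(dtype=int)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if events.sum() < 1:
        raise ValueError("no events to model")
    pid = (
        cohort["patient_id"].astype(str).to_numpy()
        if "patient_id" in cohort.columns
        else cohort.index.astype(str).to_numpy()
    )

    nodes: dict[int, Node] = {}

    def build(node_id: int, idx: np.ndarray, depth: int) -> None:
        n_ev = int(events[idx].sum())
        node = Node(
            id=node_id,
            depth=depth,
            member_ids=[str(p) for p in pid[idx]],
            n_events=n_ev,
            n_nonevents=int(idx.size - n_ev),
        )
        nodes[node_id] = node
        if (
            depth >= max_depth
            or idx.size < 2 * stopping.min_subjects
            or n_ev < 2 * stopping.min_events
            or alpha <= 0.0
        ):
            return
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(node_id,)))
        sub = cohort.iloc[idx]
        recs = pd.DataFrame(
            {"time": times[idx], "event": events[idx]}, index=sub.index
        ).join(sub[covariates])
        sel = select_split_variable(
            recs,
            covariates,
            stopping=stopping,
            n_permutations=n_permutations,
            seed=rng,
            categorical=categorical,
        )
        if sel is None:
            return
        cov, cand = sel.covariate, sel.candidate
        node.permutation_p = sel.gate_p
        node.selection_p = sel.permutation_p
        node.selected_covariate = cov
        if sel.gate_p > alpha:
            return
        vals = sub[cov]
        present = vals.notna().to_numpy()
        right = np.zeros(idx.size, dtype=bool)
        if isinstance(cand.threshold, frozenset):
            right[present] = np.isin(vals.to_numpy()[present], list(cand.threshold))
        else:
            right[present] = vals.to_numpy()[present].astype(float) > cand.threshold
        # missing values follow the larger child (ties: left)
        if (~present).any():
            n_right = int(right[present].sum())
            n_left = int(present.sum()) - n_right
            right[~present] = n_right > n_left
        left_idx, right_idx = idx[~right], idx[right]
        node.split = cand
        node.children = (2 * node_id, 2 * node_id + 1)
        build(2 * node_id, left_idx, depth + 1)
        build(2 * node_id + 1, right_idx, depth + 1)

    build(1, np.arange(len(cohort)), 0)
    return RecpamTree(
        endpoint=endpoint,
        root_id=1,
        nodes=nodes,
        stopping=stopping,
        permutations=n_permutations,
        alpha=alpha,
        max_depth=max_depth,
        seed=seed,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# Amalgamation into risk classes
# ---------------------------------------------------------------------------


def _pair_wald_p(times, events, indicator) -> float:
    """Two-sided Wald p of the class-b indicator in a two-class Cox fit.
    Separated fits count as maximally different (p = 0, never merged)."""
    fit = fit_cox(times, events, indicator[:, None])
    if not fit.converged or not np.isfinite(fit.se[0]) or fit.se[0] == 0:
        return 0.0
    z = abs(fit.coef[0]) / fit.se[0]
    return float(2.0 * stats.norm.sf(z))


def amalgamate(
    tree: RecpamTree,
    cohort: pd.DataFrame,
    amalgamation_alpha: float = 1.0,
) -> RiskClassTable:
    """Merge terminal nodes into final risk classes and rank them by HR.

    Iteratively merges the pair of current classes with the largest two-class
    Cox Wald p-value while that p exceeds ``amalgamation_alpha``; with the
    default alpha = 1 no pair ever qualifies and the leaves are the classes.
    The reference class is the one with the lowest crude event rate
    (events/person-years); HRs and Wald 95% CIs come from a single Cox fit on
    class indicators against the reference. Classes are labelled C1, C2, ...
    in decreasing-HR order (the reference last, HR = 1).
    """
    time_col, event_col = _endpoint_cols(tree.endpoint)
    times = cohort[time_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy(dtype=int)
    pid = (
        cohort["patient_id"].astype(str)
        if "patient_id" in cohort.columns
        else cohort.index.astype(str).to_series()
    )
    pos = {p: i for i, p in enumerate(pid)}

    groups: dict[tuple[int, ...], np.ndarray] = {}
    for leaf in tree.leaves:
        groups[(leaf.id,)] = np.array([pos[m] for m in leaf.member_ids], dtype=int)

    while len(groups) > 1:
        keys = sorted(groups)
        best_pair, best_p = None, -1.0
        for a, b in itertools.combinations(keys, 2):
            ia, ib = groups[a], groups[b]
            both = np.concatenate([ia, ib])
            ind = np.concatenate([np.zeros(ia.size), np.ones(ib.size)])
            p = _pair_wald_p(times[both], events[both], ind)
            if p > best_p:
                best_pair, best_p = (a, b), p
        if best_pair is None or best_p <= amalgamation_alpha:
            break
        a, b = best_pair
        groups[tuple(sorted(a + b))] = np.concatenate([groups.pop(a), groups.pop(b)])
        logger.info("amalgamated leaves %s and %s (Wald p = %.3f)", a, b, best_p)

    keys = sorted(groups)
    rates = {}
    for k in keys:
        idx = groups[k]
        rates[k] = events[idx].sum() / max(times[idx].sum(), 1e-300)
    ref_key = min(keys, key=lambda k: (rates[k], k))
    others = [k for k in keys if k != ref_key]
    X = np.column_stack(
        [np.isin(np.arange(len(cohort)), groups[k]).astype(float) for k in others]
    ) if others else np.zeros((len(cohort), 0))
    fit = fit_cox(times, events, X, names=[str(k) for k in others])

    hr_map = {ref_key: (1.0, 1.0, 1.0)}
    for k, h, lo, hi in zip(others, fit.hr, fit.ci95_low, fit.ci95_high):
        hr_map[k] = (float(h), float(lo), float(hi))
    ordered = sorted(keys, key=lambda k: (-hr_map[k][0], k))

    rows = []
    labels = pd.Series(index=pid.to_numpy(), dtype=object, name="class_id")
    for rank, k in enumerate(ordered, start=1):
        cid = f"C{rank}"
        idx = groups[k]
        rate = incidence_rate(times[idx], events[idx]) if times[idx].sum() > 0 else None
        rows.append(
            {
                "class_id": cid,
                "leaf_ids": list(k),
                "n": int(idx.size),
                "n_events": int(events[idx].sum()),
                "hr": hr_map[k][0],
                "ci95_low": hr_map[k][1],
                "ci95_high": hr_map[k][2],
                "rate_per_100py": rate.rate_per_100py if rate else float("nan"),
                "median_followup_months": float(np.median(times[idx]) * 12.0),
            }
        )
        labels.iloc[idx] = cid
        if k == ref_key:
            ref_id = cid
    return RiskClassTable(
        classes=pd.DataFrame(rows),
        reference_class_id=ref_id,
        assignment=labels,
        cox=fit,
    )


def risk_class_curves(
    cohort: pd.DataFrame, tree: RecpamTree, classes: RiskClassTable
) -> pd.DataFrame:
    """Cox-model survivor functions per final class (tidy time/class/survival)."""
    time_col, event_col = _endpoint_cols(tree.endpoint)
    curves, _ = class_survival_curves(
        cohort[time_col].to_numpy(dtype=float),
        cohort[event_col].to_numpy(dtype=int),
        classes.assignment.to_numpy(),
        reference_class=classes.reference_class_id,
    )
    return curves


# ---------------------------------------------------------------------------
# Class clinical profiles
# ---------------------------------------------------------------------------


def fisher_exact_rxc(table) -> float:
    """Exact two-sided Fisher test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed one (the
    probability-ordering rule; identical to scipy's 2x2 two-sided test).
    Intended for the small tables of a <=26-patient cohort.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    log_const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def log_prob(t: np.ndarray) -> float:
        return float(log_const - gammaln(t + 1).sum())

    lp_obs = log_prob(obs)
    r, c = obs.shape
    p_total = 0.0
    # DFS over tables with fixed margins, filling row-major; the last column
    # and last row are forced by the margins
    t = np.zeros((r, c), dtype=int)

    def rec(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray) -> None:
        nonlocal p_total
        if i == r - 1:
            if np.any(col_left < 0):
                return
            t[r - 1, :] = col_left
            lp = log_prob(t)
            if lp <= lp_obs + 1e-9:
                p_total += math.exp(lp)
            return
        if j == c - 1:
            if row_left[i] > col_left[j]:
                return
            t[i, j] = row_left[i]
            cl = col_left.copy()
            cl[j] -= row_left[i]
            rec(i + 1, 0, row_left, cl)
            return
        hi = min(row_left[i], col_left[j])
        for v in range(int(hi) + 1):
            t[i, j] = v
            rl = row_left.copy()
            rl[i] -= v
            cl = col_left.copy()
            cl[j] -= v
            rec(i, j + 1, rl, cl)

    rec(0, 0, row.copy(), col.copy())
    return min(1.0, p_total)


def class_profiles(
    cohort: pd.DataFrame,
    classes: RiskClassTable,
    clinical_covariates,
    categorical: set | None = None,
) -> pd.DataFrame:
    """Compare clinical covariates across final classes.

    Continuous covariates: Kruskal-Wallis. Categorical (non-numeric, or <= 4
    distinct values, or listed in ``categorical``): exact Fisher on the
    class x level table. Covariates with no observed values are dropped with
    a logged warning.
    """
    if classes.classes.shape[0] < 2:
        raise ValueError("need at least 2 classes to compare profiles")
    categorical = set(categorical or ())
    labels = classes.assignment
    pid = (
        cohort["patient_id"].astype(str)
        if "patient_id" in cohort.columns
        else cohort.index.astype(str).to_series()
    )
    lab = labels.loc[pid.to_numpy()].to_numpy()
    rows = []
    for cov in clinical_covariates:
        col = cohort[cov]
        ok = col.notna().to_numpy()
        if not ok.any():
            logger.warning("covariate %s has no observed values; dropped", cov)
            continue
        vals, grp = col.to_numpy()[ok], lab[ok]
        is_cat = (
            cov in categorical
            or not pd.api.types.is_numeric_dtype(col)
            or pd.unique(vals).shape[0] <= 4
        )
        if is_cat:
            tab = pd.crosstab(grp, vals)
            p = fisher_exact_rxc(tab.to_numpy())
            rows.append({"covariate": cov, "test": "fisher", "statistic": float("nan"), "p_value": p})
        else:
            samples = [vals[grp == g].astype(float) for g in pd.unique(grp)]
            samples = [s for s in samples if s.size > 0]
            if len(samples) < 2:
                logger.warning("covariate %s observed in fewer than 2 classes; dropped", cov)
                continue
            try:
                h, p = stats.kruskal(*samples)
            except ValueError:  # all values identical
                h, p = 0.0, 1.0
            rows.append({"covariate": cov, "test": "kruskal-wallis", "statistic": float(h), "p_value": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _json_threshold(thr) -> object:
    if isinstance(thr, frozenset):
        return sorted(map(str, thr))
    return float(thr)


def tree_to_dict(tree: RecpamTree, classes: RiskClassTable | None = None) -> dict:
    """JSON-serialisable view of the tree (and optionally its risk classes)."""
    nodes = {}
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        nodes[str(nid)] = {
            "depth": nd.depth,
            "member_ids": list(nd.member_ids),
            "n_events": nd.n_events,
            "n_nonevents": nd.n_nonevents,
            "permutation_p": nd.permutation_p,
            "selection_p": nd.selection_p,
            "selected_covariate": nd.selected_covariate,
            "split": None
            if nd.split is None
            else {
                "covariate": nd.split.covariate,
                "threshold": _json_threshold(nd.split.threshold),
                "statistic": nd.split.statistic,
                "hr": nd.split.hr,
                "ci95": [nd.split.ci95_low, nd.split.ci95_high],
            },
            "children": list(nd.children) if nd.children else None,
        }
    out = {
        "endpoint": tree.endpoint,
        "seed": tree.seed,
        "alpha": tree.alpha,
        "permutations": tree.permutations,
        "max_depth": tree.max_depth,
        "stopping": {
            "min_events": tree.stopping.min_events,
            "min_subjects": tree.stopping.min_subjects,
        },
        "covariates": list(tree.covariates),
        "nodes": nodes,
    }
    if classes is not None:
        out["reference_class_id"] = classes.reference_class_id
        out["classes"] = classes.classes.assign(
            leaf_ids=classes.classes["leaf_ids"].map(list)
        ).to_dict(orient="records")
    return out


def report_tree(tree: RecpamTree, classes: RiskClassTable) -> tuple[str, str]:
    """(JSON report, human-readable indented report)."""
    payload = tree_to_dict(tree, classes)
    js = json.dumps(payload, indent=2, sort_keys=True)

    lines = [
        f"Survival tree — endpoint {tree.endpoint.upper()}",
        f"permutations={tree.permutations} alpha={tree.alpha} seed={tree.seed}",
        "",
    ]

    def walk(nid: int, indent: str, label: str) -> None:
        nd = tree.nodes[nid]
        head = f"{indent}{label}node {nid}: events={nd.n_events} non-events={nd.n_nonevents}"
        if nd.split is not None:
            thr = _json_threshold(nd.split.threshold)
            head += (
                f" | split {nd.split.covariate} > {thr}"
                f" (LR={nd.split.statistic:.3f}, HR={nd.split.hr:.3f}"
                f" [{nd.split.ci95_low:.3f}, {nd.split.ci95_high:.3f}],"
                f" perm p={nd.permutation_p:.4f})"
            )
        lines.append(head)
        if nd.children:
            walk(nd.children[0], indent + "  ", "<=: ")
            walk(nd.children[1], indent + "  ", " >: ")

    walk(tree.root_id, "", "")
    lines.append("")
    lines.append(f"Risk classes (reference = {classes.reference_class_id}):")
    for _, row in classes.classes.iterrows():
        lines.append(
            f"  {row['class_id']}: leaves {row['leaf_ids']} n={row['n']}"
            f" events={row['n_events']} HR={row['hr']:.2f}"
            f" [{row['ci95_low']:.2f}, {row['ci95_high']:.2f}]"
            f" rate={row['rate_per_100py']:.1f}/100py"
            f" median follow-up={row['median_followup_months']:.1f} mo"
        )
    return js, "\n".join(lines) + "\n"
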
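"""Coelution feature detection on sample-integrated traces.

A "feature" is a resolved coelution peak group along the SEC dimension:
at peptide->protein level one distinct protein assembly state, at
protein->complex level evidence for a queried complex.  Detection runs on
traces integrated (summed) across all samples so that the same feature
boundaries apply to every condition and replicate; error rates are
controlled with randomized decoy queries and a target-decoy q-value model.

Algorithm (one deterministic realization of sliding-window coelution
scoring): member traces are smoothed with a centered moving average, the
mean pairwise Pearson correlation is computed in a sliding window, runs of
high correlation form candidate regions, peaks of the summed smoothed trace
inside a region become feature apexes (peaks closer than ``rt_height``
fractions to a higher peak are merged into it), boundaries extend to the
nearest local minima, and the coelution score is recomputed over the final
boundaries on the unsmoothed traces with greedy pruning of weakly
correlating members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger("secdiff")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ElutionFeature:
    """A detected coelution peak group (protein- or complex-level)."""

    owner_id: str
    member_ids: list
    apex_fraction: int
    left_boundary: int
    right_boundary: int
    apex_mw: float = float("nan")
    coelution_score: float = float("nan")
    completeness: float = float("nan")
    peak_area: dict = field(default_factory=dict)  # sample_id -> summed intensity
    p_value: float = float("nan")
    q_value: float = float("nan")
    is_decoy: bool = False
    is_secondary: bool = False

    def __post_init__(self):
        if not self.left_boundary <= self.apex_fraction <= self.right_boundary:
            raise ValueError("feature apex must lie within its boundaries")

    def shift(self, k):
        """Translate the feature by k fractions (used in equivariance checks)."""
        return replace(self, apex_fraction=self.apex_fraction + k,
                       left_boundary=self.left_boundary + k,
                       right_boundary=self.right_boundary + k)


@dataclass
class FeatureFinderParams:
    """Parameters of the sliding-window coelution feature finder.

    ``perturb_cutoff`` is recorded for provenance but currently has no
    effect on scoring; ``collapse_method`` selects the redundancy-collapsing
    flavor downstream.
    """

    corr_cutoff: float = 0.9
    window_size: int = 7
    rt_height: float = 1.0
    smoothing_length: int = 7
    perturb_cutoff: str = "5%"
    collapse_method: str = "apex_only"

    def __post_init__(self):
        if not (0 < self.corr_cutoff < 1):
            raise ValueError("corr_cutoff must be in (0, 1)")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")


# ---------------------------------------------------------------------------
# Trace integration
# ---------------------------------------------------------------------------

def integrate_traces(traces):
    """Sum traces fractionwise over all samples (missing treated as 0).

    Returns a dict ``member_id -> ndarray(n_fractions)`` keyed by peptide
    (for PeptideTraceSet) or protein (for ProteinTraceSet) identifiers.
    """
    summed = np.nansum(np.nan_to_num(traces.data, nan=0.0), axis=1)
    if traces.entity_axis == "peptide":
        ids = traces.peptide_ids
    else:
        ids = traces.protein_ids
    return {mid: summed[i] for i, mid in enumerate(ids)}


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _smooth(trace, length):
    """Centered moving average; edges use the fractions actually in window."""
    if length <= 1:
        return trace.astype(float)
    kernel = np.ones(length)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace, dtype=float), kernel, mode="same")
    return num / den


def _window_mean_pairwise_corr(block, window):
    """Mean pairwise Pearson correlation of rows in each sliding window.

    Returns an array over window centers (length F - window + 1); windows
    where a member has zero variance contribute correlation 0 for that pair.
    """
    m, F = block.shape
    win = sliding_window_view(block, window, axis=1)  # (m, n_pos, window)
    mean = win.mean(axis=2, keepdims=True)
    dev = win - mean
    sd = np.sqrt((dev**2).sum(axis=2))
    n_pos = win.shape[1]
    corrsum = np.zeros(n_pos)
    n_pairs = m * (m - 1) // 2
    for i in range(m):
        for j in range(i + 1, m):
            num = (dev[i] * dev[j]).sum(axis=1)
            den = sd[i] * sd[j]
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(den > 0, num / den, 0.0)
            corrsum += c
    return corrsum / n_pairs


def _mean_pairwise_corr(block):
    """Mean pairwise Pearson correlation of the rows of a 2-D block."""
    m = block.shape[0]
    if m < 2:
        return float("nan")
    sd = block.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(block)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    iu = np.triu_indices(m, k=1)
    return float(corr[iu].mean())


def _local_minima(y, lo, hi, apex):
    """Boundaries: nearest local minima of y around apex within [lo, hi]."""
    left = lo
    for k in range(apex - 1, lo - 1, -1):
        if y[k] <= y[max(k - 1, lo)] and y[k] <= y[k + 1]:
            left = k
            break
    right = hi
    for k in range(apex + 1, hi + 1):
        if y[k] <= y[min(k + 1, hi)] and y[k] <= y[k - 1]:
            right = k
            break
    return left, right


# ---------------------------------------------------------------------------
# Feature finding
# ---------------------------------------------------------------------------

def find_features(member_traces, params=None, calibration=None, owner_id="",
                  n_queried=None, is_decoy=False):
    """Detect coelution features among a group of member traces.

    Parameters
    ----------
    member_traces
        Mapping ``member_id -> ndarray(n_fractions)`` of sample-integrated
        traces (peptides of one protein, or subunit proteins of one complex).
    params
        :class:`FeatureFinderParams`; defaults follow standard settings.
    calibration
        Optional :class:`FractionCalibration`; fills ``apex_mw``.
    n_queried
        Number of queried members (denominator of completeness); defaults
        to ``len(member_traces)``.
    """
    params = params or FeatureFinderParams()
    ids = list(member_traces)
    if len(ids) < 2:
        logger.debug("owner %s has <2 member traces; no features", owner_id)
        return []
    block = np.vstack([np.nan_to_num(np.asarray(member_traces[i], dtype=float), nan=0.0)
                       for i in ids])
    F = block.shape[1]
    w = params.window_size
    if F < w:
        return []
    n_queried = n_queried or len(ids)

    smoothed = np.vstack([_smooth(t, params.smoothing_length) for t in block])
    total = smoothed.sum(axis=0)

    corr = _window_mean_pairwise_corr(smoothed, w)
    half = w // 2
    centers = np.arange(half, F - half)
    high = corr >= params.corr_cutoff

    features = []
    # contiguous runs of high-correlation window centers -> candidate regions
    run_start = None
    runs = []
    for k, flag in enumerate(high):
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            runs.append((run_start, k - 1))
            run_start = None
    if run_start is not None:
        runs.append((run_start, len(high) - 1))

    for r0, r1 in runs:
        lo = max(centers[r0] - half, 0)
        hi = min(centers[r1] + half, F - 1)
        seg = total[lo:hi + 1]
        # local maxima of the summed smoothed trace within the region
        peaks = [k for k in range(len(seg))
                 if (k == 0 or seg[k] >= seg[k - 1])
                 and (k == len(seg) - 1 or seg[k] > seg[k + 1])]
        if not peaks:
            peaks = [int(np.argmax(seg))]
        # merge peaks closer than rt_height fractions into the higher one
        peaks = sorted(peaks, key=lambda k: -seg[k])
        kept = []
        for k in peaks:
            if all(abs(k - q) > params.rt_height for q in kept):
                kept.append(k)
        for k in sorted(kept):
            apex = lo + k
            left, right = _local_minima(total, lo, hi, apex)
            if right - left + 1 < 3:
                # Pearson correlation over <3 fractions is degenerate
                continue
            members = list(ids)
            sub = block[:, left:right + 1]
            score = _mean_pairwise_corr(sub)
            # greedily drop the member correlating least with the rest
            while score < params.corr_cutoff and len(members) > 2:
                m = len(members)
                sd = sub.std(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cm = np.corrcoef(sub)
                cm = np.where(np.isfinite(cm), cm, 0.0)
                cm[sd == 0, :] = 0.0
                cm[:, sd == 0] = 0.0
                np.fill_diagonal(cm, 0.0)
                mean_to_rest = cm.sum(axis=1) / (m - 1)
                drop = int(np.argmin(mean_to_rest))
                members.pop(drop)
                sub = np.delete(sub, drop, axis=0)
                score = _mean_pairwise_corr(sub)
            if score < params.corr_cutoff or len(members) < 2:
                continue
            mw = float(calibration.fraction_to_mw(apex + 1)) if calibration else float("nan")
            features.append(ElutionFeature(
                owner_id=owner_id, member_ids=members,
                apex_fraction=apex + 1, left_boundary=left + 1,
                right_boundary=right + 1, apex_mw=mw,
                coelution_score=score,
                completeness=len(members) / n_queried,
                is_decoy=is_decoy,
            ))
    return features


def attach_peak_areas(features, traces):
    """Fill per-sample peak areas (member intensities summed over the
    feature's boundary range, missing as 0)."""
    if traces.entity_axis == "peptide":
        index = {p: i for i, p in enumerate(traces.peptide_ids)}
    else:
        index = {p: i for i, p in enumerate(traces.protein_ids)}
    filled = np.nan_to_num(traces.data, nan=0.0)
    for feat in features:
        idx = [index[m] for m in feat.member_ids if m in index]
        lo, hi = feat.left_boundary - 1, feat.right_boundary
        block = filled[idx, :, lo:hi].sum(axis=(0, 2))
        feat.peak_area = dict(zip(traces.sample_ids, block.tolist()))
    return features


# ---------------------------------------------------------------------------
# Decoys and q-values
# ---------------------------------------------------------------------------

def make_peptide_decoys(traces, seed):
    """Random peptide assignments as a decoy model for protein features.

    One decoy "protein" per target protein, matching the target's peptide
    count, with the decoy's peptides drawn from distinct real proteins
    (sampling without replacement within a decoy).  Deterministic under
    ``seed``.

    Returns a dict ``decoy_id -> list of peptide_ids``.
    """
    rng = np.random.default_rng(seed)
    proteins = {}
    for pep, prot in zip(traces.peptide_ids, traces.protein_ids):
        proteins.setdefault(prot, []).append(pep)
    prot_ids = sorted(proteins)
    if len(prot_ids) < 2:
        raise ValueError("need >=2 proteins to build peptide decoys")
    decoys = {}
    for t, prot in enumerate(prot_ids):
        k = len(proteins[prot])
        if k > len(prot_ids):
            raise ValueError(
                f"cannot draw {k} peptides from distinct proteins "
                f"({len(prot_ids)} proteins available)"
            )
        src = rng.choice(len(prot_ids), size=k, replace=False)
        members = []
        for s in src:
            peps = proteins[prot_ids[s]]
            members.append(peps[rng.integers(len(peps))])
        decoys[f"DECOY_{t}_{prot}"] = members
    return decoys


def estimate_q_values(target_features, decoy_features, key=None):
    """Target-decoy q-values for coelution features.

    For a score threshold s, ``FDR(s) = (#decoys >= s) / (#targets >= s)``;
    a feature's q-value is the minimum FDR over thresholds at or below its
    own score (monotone step-up), and its p-value is the empirical decoy
    exceedance ``(#decoys >= s + 1) / (#decoys + 1)``.

    ``key`` extracts the ranking score (default: coelution score); pass a
    tuple-valued key for composite ranking (e.g. completeness then score
    for complex features).
    """
    if not decoy_features:
        raise ValueError("empty decoy list: cannot control FDR")
    key = key or (lambda f: f.coelution_score)
    tscores = [key(f) for f in target_features]
    dscores = sorted(key(f) for f in decoy_features)
    order = sorted(range(len(tscores)),
                   key=lambda i: _rank_key(tscores[i]), reverse=True)

    n_d = len(dscores)
    fdrs = np.empty(len(order))
    for rank, idx in enumerate(order):
        s = tscores[idx]
        n_decoys_ge = n_d - _bisect_ge(dscores, s)
        fdrs[rank] = n_decoys_ge / (rank + 1)
        target_features[idx].p_value = (n_decoys_ge + 1) / (n_d + 1)
    qs = np.minimum.accumulate(np.minimum(fdrs, 1.0)[::-1])[::-1]
    for rank, idx in enumerate(order):
        target_features[idx].q_value = float(qs[rank])
    return target_features


def _rank_key(s):
    return s if isinstance(s, tuple) else (s,)


def _bisect_ge(sorted_scores, s):
    """Index of the first element >= s in an ascending list (tuple-aware)."""
    import bisect
    return bisect.bisect_left([_rank_key(x) for x in sorted_scores], _rank_key(s))


def detect_protein_features(traces, params=None, calibration=None, seed=0,
                            fdr=None):
    """Protein-centric feature detection over a whole trace set.

    Integrates peptide traces across samples, finds features per protein,
    scores random peptide-assignment decoys identically, and estimates
    q-values.  If ``fdr`` is given, only target features with q <= fdr are
    returned; otherwise all scored target features.
    """
    params = params or FeatureFinderParams()
    integrated = integrate_traces(traces)
    targets, decoy_feats = [], []
    proteins = {}
    for pep, prot in zip(traces.peptide_ids, traces.protein_ids):
        proteins.setdefault(prot, []).append(pep)
    for prot, peps in sorted(proteins.items()):
        sub = {p: integrated[p] for p in peps}
        targets.extend(find_features(sub, params, calibration, owner_id=prot))
    try:
        decoy_groups = make_peptide_decoys(traces, seed)
    except ValueError as exc:
        logger.warning("no decoys built (%s); q-values not decoy-controlled", exc)
        decoy_groups = {}
    for did, peps in decoy_groups.items():
        sub = {p: integrated[p] for p in peps}
        decoy_feats.extend(
            find_features(sub, params, calibration, owner_id=did, is_decoy=True)
        )
    if decoy_feats:
        estimate_q_values(targets, decoy_feats)
    else:
        # no decoy reached a scoreable feature: all targets maximally confident
        for f in targets:
            f.q_value = 0.0
            f.p_value = 1.0 / (len(decoy_feats) + 1)
    if fdr is not None:
        targets = [f for f in targets if f.q_value <= fdr]
    attach_peak_areas(targets, traces)
    return targets, decoy_feats


def features_to_frame(features):
    """Tabular view of a feature list (member lists semicolon-joined)."""
    import pandas as pd
    rows = []
    for f in features:
        rows.append({
            "owner_id": f.owner_id,
            "members": ";".join(map(str, f.member_ids)),
            "n_members": len(f.member_ids),
            "apex_fraction": f.apex_fraction,
            "left_boundary": f.left_boundary,
            "right_boundary": f.right_boundary,
            "apex_mw": f.apex_mw,
            "coelution_score": f.coelution_score,
            "completeness": f.completeness,
            "p_value": f.p_value,
            "q_value": f.q_value,
            "is_decoy": f.is_decoy,
            "is_secondary": f.is_secondary,
        })
    return pd.DataFrame(rows)
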
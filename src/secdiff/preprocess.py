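"""Peptide trace preprocessing: spline imputation of internal gaps, cyclic
loess normalization across samples, confidence filtering of peptides, and
top-N protein quantification.

The steps are applied in this order and each is available separately; the
filtering step is order-dependent (consecutive-detection rule before sibling
correlation rules) and idempotent on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import PeptideTraceSet, ProteinTraceSet

logger = logging.getLogger("secdiff")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_internal_gaps(traces):
    """Impute missing cells flanked by measured fractions on both sides.

    Eligibility: a missing (peptide, sample, fraction) cell is imputed only
    when both the previous and the following fraction hold measured values.
    Eligible cells receive the value of a cubic interpolating spline fitted
    per (peptide, sample) over the measured fractions, floored at zero.
    Traces with fewer than 4 measured points fall back to linear
    interpolation.  Measured cells are never altered.

    Returns
    -------
    (PeptideTraceSet, ndarray of bool)
        The imputed trace set and a flag tensor marking imputed cells.
    """
    out = traces.copy()
    imputed = np.zeros(out.data.shape, dtype=bool)
    x = np.arange(out.n_fractions)
    for p in range(out.n_peptides):
        for s in range(out.n_samples):
            y = out.data[p, s]
            meas = np.isfinite(y)
            if meas.sum() < 2:
                continue
            eligible = ~meas
            eligible[0] = eligible[-1] = False
            eligible[1:-1] &= meas[:-2] & meas[2:]
            if not eligible.any():
                continue
            xm, ym = x[meas], y[meas]
            if meas.sum() >= 4:
                fit = CubicSpline(xm, ym)(x[eligible])
            else:
                logger.debug("short trace (%d points): linear fallback", meas.sum())
                fit = np.interp(x[eligible], xm, ym)
            out.data[p, s, eligible] = np.maximum(fit, 0.0)
            imputed[p, s, eligible] = True
    return out, imputed


# ---------------------------------------------------------------------------
# Cyclic loess normalization
# ---------------------------------------------------------------------------

def cyclic_loess_normalize(traces, cycles=3, span=0.7, min_shared=100):
    """Normalize intensities across samples by cyclic loess.

    Works on log2 intensities of the per-sample vectors formed by all
    peptide x fraction cells measured in both samples of a pair.  For every
    sample pair (i, j), a loess curve of M = x_i - x_j on A = (x_i + x_j)/2
    is fitted; half the fitted M is subtracted from sample i and added to
    sample j.  All pairs are visited per cycle and the sweep is repeated
    ``cycles`` times, after which the corrections have essentially converged.
    Output intensities are returned on the original linear scale.

    A sample sharing fewer than ``min_shared`` measured cells with every
    other sample passes through unnormalized (with a warning).
    """
    out = traces.copy()
    n_samp = out.n_samples
    if n_samp < 2:
        raise ValueError("cyclic loess needs >=2 samples")
    # flattened (peptide*fraction) x sample matrix of log2 intensities
    flat = out.data.transpose(0, 2, 1).reshape(-1, n_samp)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.where(flat > 0, np.log2(flat), np.nan)

    shared = np.zeros((n_samp, n_samp), dtype=int)
    meas = np.isfinite(log2)
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            shared[i, j] = shared[j, i] = int((meas[:, i] & meas[:, j]).sum())
    active = np.array([
        any(shared[i, j] >= min_shared for j in range(n_samp) if j != i)
        for i in range(n_samp)
    ])
    for i, ok in enumerate(active):
        if not ok:
            logger.warning(
                "sample %s shares <%d measured cells with every other sample; "
                "left unnormalized", out.sample_ids[i], min_shared,
            )

    for _ in range(cycles):
        for i in range(n_samp):
            for j in range(i + 1, n_samp):
                if not (active[i] and active[j]) or shared[i, j] < min_shared:
                    continue
                both = meas[:, i] & meas[:, j]
                a = 0.5 * (log2[both, i] + log2[both, j])
                m = log2[both, i] - log2[both, j]
                delta = 0.01 * (a.max() - a.min()) if len(a) > 1 else 0.0
                fitted = lowess(m, a, frac=span, delta=delta, return_sorted=False)
                log2[both, i] -= fitted / 2.0
                log2[both, j] += fitted / 2.0

    norm = np.where(meas, np.exp2(log2), flat)
    out.data = norm.reshape(out.n_peptides, out.n_fractions, n_samp).transpose(0, 2, 1)
    return out


# ---------------------------------------------------------------------------
# Peptide filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts and drop lists for the sequential peptide filter rules."""

    n_input_peptides: int = 0
    n_after_consecutive: int = 0
    n_after_sibling_corr: int = 0
    n_after_min_peptides: int = 0
    dropped_consecutive: list = field(default_factory=list)
    dropped_sibling_corr: list = field(default_factory=list)
    dropped_min_peptides: list = field(default_factory=list)

    def summary(self):
        return {
            "n_input_peptides": self.n_input_peptides,
            "n_after_consecutive": self.n_after_consecutive,
            "n_after_sibling_corr": self.n_after_sibling_corr,
            "n_after_min_peptides": self.n_after_min_peptides,
        }


def _max_run(mask):
    """Longest run of True in a boolean vector."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def sibling_correlations(traces):
    """Pearson correlation matrix between sibling peptides of each protein.

    Correlations are computed on the concatenation of each peptide's
    full-grid traces across all samples, with missing treated as zero
    (inside the correlation computation only).

    Returns a dict ``protein_id -> (peptide_ids, corr_matrix)``.
    """
    if traces.n_peptides == 0:
        return {}
    filled = np.nan_to_num(traces.data, nan=0.0)
    flat = filled.reshape(traces.n_peptides, -1)
    out = {}
    for prot in pd_unique(traces.protein_ids):
        idx = np.flatnonzero(traces.protein_ids == prot)
        if len(idx) < 2:
            out[prot] = (list(traces.peptide_ids[idx]), np.ones((len(idx), len(idx))))
            continue
        block = flat[idx]
        sd = block.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(block)
        corr[~np.isfinite(corr)] = 0.0
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        np.fill_diagonal(corr, 1.0)
        out[prot] = (list(traces.peptide_ids[idx]), corr)
    return out


def pd_unique(values):
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def filter_peptides(traces, design=None, min_consecutive=3,
                    max_sibling_corr_min=0.5, avg_sibling_corr_min=0.2):
    """Remove low-confidence peptides by the three sequential rules.

    1. keep a peptide iff some single sample contains at least
       ``min_consecutive`` consecutive measured fractions;
    2. keep a peptide iff its maximum sibling-peptide correlation is at
       least ``max_sibling_corr_min``;
    3. and its mean sibling correlation is at least ``avg_sibling_corr_min``.

    Rules 2 and 3 use Pearson correlations over the concatenated full-grid
    traces across all samples (missing as 0).  Proteins left with fewer than
    two proteotypic peptides are removed entirely.
    """
    report = FilterReport(n_input_peptides=traces.n_peptides)

    meas = np.isfinite(traces.data)
    keep1 = np.array([
        any(_max_run(meas[p, s]) >= min_consecutive for s in range(traces.n_samples))
        for p in range(traces.n_peptides)
    ])
    report.dropped_consecutive = list(traces.peptide_ids[~keep1])
    traces1 = traces.subset_peptides(traces.peptide_ids[keep1])
    report.n_after_consecutive = traces1.n_peptides

    keep_ids = []
    for prot, (peps, corr) in sibling_correlations(traces1).items():
        if len(peps) < 2:
            report.dropped_sibling_corr.extend(peps)
            continue
        off = corr - np.eye(len(peps)) * 2  # exclude self from max
        for k, pep in enumerate(peps):
            sib = np.delete(corr[k], k)
            if off[k].max() >= max_sibling_corr_min and sib.mean() >= avg_sibling_corr_min:
                keep_ids.append(pep)
            else:
                report.dropped_sibling_corr.append(pep)
    keep_ids = [p for p in traces1.peptide_ids if p in set(keep_ids)]
    traces2 = traces1.subset_peptides(keep_ids)
    report.n_after_sibling_corr = traces2.n_peptides

    counts = {}
    for prot in traces2.protein_ids:
        counts[prot] = counts.get(prot, 0) + 1
    final_ids = [
        p for p, prot in zip(traces2.peptide_ids, traces2.protein_ids)
        if counts[prot] >= 2
    ]
    report.dropped_min_peptides = [
        p for p in traces2.peptide_ids if p not in set(final_ids)
    ]
    out = traces2.subset_peptides(final_ids)
    report.n_after_min_peptides = out.n_peptides
    return out, report


# ---------------------------------------------------------------------------
# Protein quantification
# ---------------------------------------------------------------------------

def quantify_proteins(traces, top_n=2):
    """Protein traces from the top-N most intense peptides per protein.

    Peptides are ranked by total intensity summed over all samples and
    fractions; the same ``top_n`` peptides (ties broken by lexicographic
    peptide_id, for determinism) are used for every sample, and the protein
    trace is their fractionwise sum.  Cells where every selected peptide is
    missing stay missing.
    """
    totals = np.nansum(np.nan_to_num(traces.data, nan=0.0), axis=(1, 2))
    selected = {}
    for prot in pd_unique(traces.protein_ids):
        idx = np.flatnonzero(traces.protein_ids == prot)
        order = sorted(idx, key=lambda i: (-totals[i], traces.peptide_ids[i]))
        selected[prot] = [traces.peptide_ids[i] for i in order[:top_n]]

    protein_ids = list(selected)
    data = np.full((len(protein_ids), traces.n_samples, traces.n_fractions), np.nan)
    for k, prot in enumerate(protein_ids):
        idx = [np.flatnonzero(traces.peptide_ids == p)[0] for p in selected[prot]]
        block = traces.data[idx]
        allnan = np.all(np.isnan(block), axis=0)
        summed = np.nansum(np.nan_to_num(block, nan=0.0), axis=0)
        data[k] = np.where(allnan, np.nan, summed)
    return ProteinTraceSet(data, protein_ids, traces.sample_ids, selected)
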
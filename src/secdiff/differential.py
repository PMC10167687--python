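"""Feature-specific, global and FMF differential quantification with
peptide -> protein (and protein -> complex) p-value aggregation.

Differential testing of a detected coelution feature proceeds in six
steps: (i) per-peptide feature intensities are computed by summing
fractions across the feature range, with missing cells imputed uniformly
between zero and the peptide's minimum detected signal; (ii) per-condition
mean intensities; (iii) log2 fold change of the condition means; (iv) a
two-sided Welch t test on the per-replicate summed intensities (a paired
per-fraction t test when a condition lacks replicates); (v) aggregation of
peptide-level statistics to the protein (and, for complexes, further to
the complex) via the median fold change and the fold-change-adjusted
median p-value referred to a beta order-statistic null; (vi)
Benjamini-Hochberg correction across entities.

Global differential analysis is the same procedure applied over the whole
fractionation range; the feature-specific mass fraction (FMF) instead
compares the bounded ratio of in-feature to total signal with the beta
regression likelihood-ratio test used for AMF values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amf import beta_lrt, bh_adjust, transform_unit_interval

logger = logging.getLogger("secdiff")


@dataclass
class DifferentialResult:
    """Differential statistics for one entity (feature, protein or complex)."""

    entity_id: str
    level: str                      # feature | protein_global | protein_FMF | complex
    log2fc: float = float("nan")
    p_value: float = float("nan")
    adjusted_p: float = float("nan")
    mean_intensity_a: float = float("nan")
    mean_intensity_b: float = float("nan")
    diff: float = float("nan")      # FMF level only: mean_a - mean_b
    n_members_aggregated: int = 0
    significant: bool = False
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Step (i): member intensities within a feature range, with imputation
# ---------------------------------------------------------------------------

def impute_differential(traces, member_ids, rng):
    """Impute missing cells by Uniform(0, min detected signal of peptide).

    Returns a dense (member x sample x fraction) array; members never
    detected anywhere are excluded (their rows dropped, ids returned).
    """
    if traces.entity_axis == "peptide":
        index = {p: i for i, p in enumerate(traces.peptide_ids)}
    else:
        index = {p: i for i, p in enumerate(traces.protein_ids)}
    kept, blocks = [], []
    for m in member_ids:
        if m not in index:
            continue
        block = traces.data[index[m]].copy()
        finite = np.isfinite(block)
        if not finite.any():
            logger.info("member %s never detected; excluded from differential", m)
            continue
        lo = block[finite].min()
        miss = ~finite
        block[miss] = rng.uniform(0.0, lo, size=int(miss.sum()))
        kept.append(m)
        blocks.append(block)
    if not blocks:
        return [], np.empty((0, traces.n_samples, traces.n_fractions))
    return kept, np.stack(blocks)


def feature_member_intensity(feature, traces, rng):
    """Per-member, per-sample summed intensity over the feature range.

    Missing cells are first imputed (uniform below the member's minimum
    detected signal); the feature intensity is the sum over the closed
    fraction interval [left_boundary, right_boundary].
    """
    members, block = impute_differential(traces, feature.member_ids, rng)
    lo, hi = feature.left_boundary - 1, feature.right_boundary
    sums = block[:, :, lo:hi].sum(axis=2)
    return members, pd.DataFrame(sums, index=members, columns=traces.sample_ids), block


# ---------------------------------------------------------------------------
# Steps (ii)-(iv): per-member fold changes and t tests
# ---------------------------------------------------------------------------

def _member_stats(intensities, block, feature_range, samp_a, samp_b, columns):
    """log2FC and t-test p-value per member between two condition groups."""
    ia = [columns.index(s) for s in samp_a]
    ib = [columns.index(s) for s in samp_b]
    out = []
    for k in range(intensities.shape[0]):
        xa, xb = intensities[k, ia], intensities[k, ib]
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        with np.errstate(divide="ignore"):
            log2fc = float(np.log2(mean_a / mean_b)) if mean_b > 0 and mean_a > 0 \
                else (np.inf if mean_a > 0 else (-np.inf if mean_b > 0 else 0.0))
        if min(len(xa), len(xb)) >= 2:
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                p = 1.0  # zero variance in both groups
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False)[1])
        else:
            # no replicates: paired per-fraction t test across conditions
            lo, hi = feature_range
            fa = block[k][:, lo:hi][ia].mean(axis=0) if len(ia) > 1 else block[k][ia[0], lo:hi]
            fb = block[k][:, lo:hi][ib].mean(axis=0) if len(ib) > 1 else block[k][ib[0], lo:hi]
            if np.allclose(fa, fb):
                p = 1.0
            else:
                p = float(stats.ttest_rel(fa, fb)[1])
        if not np.isfinite(p):
            p = 1.0
        out.append((log2fc, p, mean_a, mean_b))
    return out


# ---------------------------------------------------------------------------
# Step (v): aggregation to the parent entity
# ---------------------------------------------------------------------------

def aggregate_to_parent(log2fcs, p_values):
    """Median fold change and fold-change-adjusted median p-value.

    The parent log2FC is the median of the member fold changes.  Member
    p-values whose fold-change sign opposes the parent median are replaced
    by 1 - p (direction adjustment); the parent p-value is the CDF of
    Beta(j, m - j + 1) — the null of the j-th order statistic of m
    uniforms, j = ceil(m / 2) — evaluated at the j-th smallest adjusted
    p-value.
    """
    fc = np.asarray(log2fcs, dtype=float)
    p = np.asarray(p_values, dtype=float)
    m = len(fc)
    if m == 0:
        raise ValueError("cannot aggregate zero members")
    parent_fc = float(np.median(fc))
    sign = np.sign(parent_fc)
    adj = p.copy()
    if sign != 0:
        discordant = np.sign(fc) == -sign  # sign ties stay concordant
        adj[discordant] = 1.0 - adj[discordant]
    j = int(np.ceil(m / 2))
    med = float(np.sort(adj)[j - 1])
    parent_p = float(stats.beta.cdf(med, j, m - j + 1))
    return parent_fc, parent_p


# ---------------------------------------------------------------------------
# Feature-level and global differential analysis
# ---------------------------------------------------------------------------

def feature_differential(feature, traces, design, condition_a, condition_b,
                         rng=None, full_range=False, level="feature"):
    """Differential result for one feature (or the global range).

    Runs steps (i)-(v) for the peptides of the feature's owner protein
    within the feature range (the full grid when ``full_range``) and
    aggregates to a single protein-level result.  BH correction across
    entities is applied by the caller (:func:`differential_table`).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    samp_a = design.samples_for(condition_a)
    samp_b = design.samples_for(condition_b)
    if full_range:
        from dataclasses import replace
        feature = replace(feature, left_boundary=1, apex_fraction=1,
                          right_boundary=traces.n_fractions)
    members, table, block = feature_member_intensity(feature, traces, rng)
    res = DifferentialResult(entity_id=feature.owner_id, level=level)
    if not members:
        res.flags.append("no_detected_members")
        return res
    lo, hi = feature.left_boundary - 1, feature.right_boundary
    per_member = _member_stats(
        table.to_numpy(), block, (lo, hi), samp_a, samp_b, list(table.columns)
    )
    fcs = [s[0] for s in per_member]
    ps = [s[1] for s in per_member]
    finite = [k for k, f in enumerate(fcs) if np.isfinite(f)]
    if not finite:
        res.flags.append("no_finite_fold_changes")
        return res
    fc, p = aggregate_to_parent([fcs[k] for k in finite], [ps[k] for k in finite])
    res.log2fc, res.p_value = fc, p
    res.n_members_aggregated = len(finite)
    res.mean_intensity_a = float(np.mean([per_member[k][2] for k in finite]))
    res.mean_intensity_b = float(np.mean([per_member[k][3] for k in finite]))
    return res


def global_differential(feature_or_protein, traces, design, condition_a,
                        condition_b, rng=None, protein_peptides=None):
    """Global differential analysis across the entire fractionation range.

    Accepts either an ElutionFeature (its owner's peptides are used) or a
    protein id with ``protein_peptides`` listing its peptides.  Equivalent
    to a standard abundance-based proteomics comparison.
    """
    from .features import ElutionFeature
    if isinstance(feature_or_protein, ElutionFeature):
        feature = feature_or_protein
    else:
        feature = ElutionFeature(
            owner_id=feature_or_protein, member_ids=list(protein_peptides),
            apex_fraction=1, left_boundary=1, right_boundary=traces.n_fractions,
        )
    return feature_differential(
        feature, traces, design, condition_a, condition_b, rng=rng,
        full_range=True, level="protein_global",
    )


def differential_table(results, log2fc_min=1.0, alpha=0.05):
    """BH adjustment and significance calls across a list of results.

    Significance requires ``|log2FC| >= log2fc_min`` and BH-adjusted
    p <= ``alpha``.
    """
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        adj = bh_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
            r.significant = (
                np.isfinite(r.log2fc)
                and abs(r.log2fc) >= log2fc_min
                and r.adjusted_p <= alpha
            )
    return results


def results_frame(results):
    return pd.DataFrame([
        {
            "entity_id": r.entity_id, "level": r.level, "log2fc": r.log2fc,
            "diff": r.diff, "p_value": r.p_value, "adjusted_p": r.adjusted_p,
            "mean_intensity_a": r.mean_intensity_a,
            "mean_intensity_b": r.mean_intensity_b,
            "n_members_aggregated": r.n_members_aggregated,
            "significant": r.significant, "flags": ";".join(r.flags),
        }
        for r in results
    ])


# ---------------------------------------------------------------------------
# Feature-specific mass fraction (FMF)
# ---------------------------------------------------------------------------

def compute_fmf(feature, traces, member_ids=None):
    """Per-member, per-sample feature-specific mass fractions.

    ``y = (member signal within the feature range) / (member total signal)``
    per sample; samples with zero total signal for a member are excluded
    (NaN).  Returns a member x sample DataFrame.
    """
    if traces.entity_axis == "peptide":
        index = {p: i for i, p in enumerate(traces.peptide_ids)}
    else:
        index = {p: i for i, p in enumerate(traces.protein_ids)}
    members = [m for m in (member_ids or feature.member_ids) if m in index]
    lo, hi = feature.left_boundary - 1, feature.right_boundary
    rows = {}
    for m in members:
        block = np.nan_to_num(traces.data[index[m]], nan=0.0)
        total = block.sum(axis=1)
        inside = block[:, lo:hi].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            # clip guards the [0,1] bound against summation-order rounding
            y = np.clip(np.where(total > 0, inside / total, np.nan), 0.0, 1.0)
        rows[m] = dict(zip(traces.sample_ids, y))
    return pd.DataFrame(rows).T.reindex(columns=traces.sample_ids)


def fmf_differential(feature, traces, design, condition_a, condition_b,
                     min_diff=0.3, alpha=None):
    """Protein-level FMF differential result for one feature.

    Member-level FMF values are compared across conditions with the beta
    regression LRT (after extreme shrinkage); member statistics are
    aggregated with the difference-adjusted median p-value and a beta
    order-statistic null, the diff being the median member diffFMF.  BH
    and the significance thresholds (|diffFMF| >= ``min_diff``, adjusted
    p <= 0.05) are applied across features by the caller.
    """
    samp_a = design.samples_for(condition_a)
    samp_b = design.samples_for(condition_b)
    n = len(samp_a) + len(samp_b)
    values = compute_fmf(feature, traces)
    diffs, ps = [], []
    for m, row in values.iterrows():
        ya = row[samp_a].to_numpy(dtype=float)
        yb = row[samp_b].to_numpy(dtype=float)
        ya, yb = ya[np.isfinite(ya)], yb[np.isfinite(yb)]
        if len(ya) < 2 or len(yb) < 2:
            continue
        diffs.append(float(ya.mean() - yb.mean()))
        y = transform_unit_interval(np.concatenate([ya, yb]), n)
        ps.append(beta_lrt(y, np.array(["A"] * len(ya) + ["B"] * len(yb))))
    res = DifferentialResult(entity_id=feature.owner_id, level="protein_FMF")
    if not diffs:
        res.flags.append("insufficient_samples")
        return res
    diff, p = aggregate_to_parent(diffs, ps)
    res.diff, res.p_value = diff, p
    res.n_members_aggregated = len(diffs)
    return res


def fmf_table(results, min_diff=0.3, alpha=0.05):
    """BH adjustment and significance calls for FMF results."""
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        adj = bh_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
            r.significant = abs(r.diff) >= min_diff and r.adjusted_p <= alpha
    return results
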
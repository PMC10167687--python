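"""Core domain types, file I/O, molecular-weight calibration and global QC.

The central container is :class:`PeptideTraceSet`: a dense peptide x sample x
fraction intensity tensor derived from SEC (size exclusion chromatography)
cofractionation MS experiments.  Missing values are encoded as NaN and are
distinct from zero intensity; raw zeros on input are treated as missing
because downstream imputation rules distinguish "not detected" from signal.

Fraction indices are 1-based and refer to collected SEC fractions; all
fraction ranges in the package are closed intervals ``[left, right]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("secdiff")

TRACE_COLUMNS = ["peptide_id", "protein_id", "sample_id", "fraction_index", "intensity"]


class SecDiffError(ValueError):
    """Raised on invalid inputs (duplicate keys, ambiguous peptides, ...)."""


# ---------------------------------------------------------------------------
# Trace containers
# ---------------------------------------------------------------------------

class PeptideTraceSet:
    """Peptide-level SEC elution traces across samples.

    Parameters
    ----------
    data
        Array of shape ``(n_peptides, n_samples, n_fractions)``; NaN marks
        missing (not detected) cells.
    peptide_ids, protein_ids
        Aligned arrays; every peptide maps to exactly one protein
        (proteotypic peptides only).
    sample_ids
        Sample identifiers, aligned with axis 1.
    """

    entity_axis = "peptide"

    def __init__(self, data, peptide_ids, protein_ids, sample_ids):
        self.data = np.asarray(data, dtype=float)
        self.peptide_ids = np.asarray(peptide_ids, dtype=object)
        self.protein_ids = np.asarray(protein_ids, dtype=object)
        self.sample_ids = list(sample_ids)
        if self.data.ndim != 3:
            raise SecDiffError("trace tensor must be 3-dimensional")
        if self.data.shape[0] != len(self.peptide_ids):
            raise SecDiffError("peptide_ids length mismatch")
        if len(self.peptide_ids) != len(self.protein_ids):
            raise SecDiffError("protein_ids length mismatch")
        if self.data.shape[1] != len(self.sample_ids):
            raise SecDiffError("sample_ids length mismatch")
        self._pep_index = {p: i for i, p in enumerate(self.peptide_ids)}
        self._samp_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_peptides(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def n_fractions(self):
        return self.data.shape[2]

    @property
    def fractions(self):
        """1-based fraction grid."""
        return np.arange(1, self.n_fractions + 1)

    def protein_of(self, peptide_id):
        return self.protein_ids[self._pep_index[peptide_id]]

    def sample_index(self, sample_id):
        return self._samp_index[sample_id]

    def peptides_of_protein(self, protein_id):
        mask = self.protein_ids == protein_id
        return list(self.peptide_ids[mask])

    def subset_peptides(self, peptide_ids):
        idx = [self._pep_index[p] for p in peptide_ids]
        return PeptideTraceSet(
            self.data[idx], self.peptide_ids[idx], self.protein_ids[idx], self.sample_ids
        )

    def copy(self):
        return PeptideTraceSet(
            self.data.copy(), self.peptide_ids.copy(), self.protein_ids.copy(),
            list(self.sample_ids),
        )

    # -- I/O -----------------------------------------------------------------
    def to_long(self, include_missing=False):
        """Long-format DataFrame; missing cells dropped unless requested."""
        p, s, f = np.meshgrid(
            np.arange(self.n_peptides), np.arange(self.n_samples),
            np.arange(self.n_fractions), indexing="ij",
        )
        df = pd.DataFrame({
            "peptide_id": self.peptide_ids[p.ravel()],
            "protein_id": self.protein_ids[p.ravel()],
            "sample_id": np.asarray(self.sample_ids, dtype=object)[s.ravel()],
            "fraction_index": f.ravel() + 1,
            "intensity": self.data.ravel(),
        })
        if not include_missing:
            df = df[np.isfinite(df["intensity"].to_numpy())].reset_index(drop=True)
        return df

    def write_tsv(self, path):
        self.to_long().to_csv(path, sep="\t", index=False)


class ProteinTraceSet:
    """Protein-level traces (summed selected peptides), same layout as peptides."""

    entity_axis = "protein"

    def __init__(self, data, protein_ids, sample_ids, selected_peptides=None):
        self.data = np.asarray(data, dtype=float)
        self.protein_ids = np.asarray(protein_ids, dtype=object)
        self.sample_ids = list(sample_ids)
        # same peptides used for every sample of a protein, by construction
        self.selected_peptides = selected_peptides or {}
        self._prot_index = {p: i for i, p in enumerate(self.protein_ids)}
        self._samp_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_proteins(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def n_fractions(self):
        return self.data.shape[2]

    def protein_index(self, protein_id):
        return self._prot_index[protein_id]

    def sample_index(self, sample_id):
        return self._samp_index[sample_id]

    def trace(self, protein_id, sample_id):
        return self.data[self._prot_index[protein_id], self._samp_index[sample_id]]

    def to_long(self):
        p, s, f = np.meshgrid(
            np.arange(self.n_proteins), np.arange(self.n_samples),
            np.arange(self.n_fractions), indexing="ij",
        )
        df = pd.DataFrame({
            "protein_id": self.protein_ids[p.ravel()],
            "sample_id": np.asarray(self.sample_ids, dtype=object)[s.ravel()],
            "fraction_index": f.ravel() + 1,
            "intensity": self.data.ravel(),
        })
        return df[np.isfinite(df["intensity"].to_numpy())].reset_index(drop=True)

    def write_tsv(self, path):
        self.to_long().to_csv(path, sep="\t", index=False)


@dataclass
class DesignMatrix:
    """Sample -> (condition, replicate) assignment."""

    frame: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self):
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(self.frame.columns):
            raise SecDiffError(f"design matrix needs columns {sorted(required)}")
        if self.frame["sample_id"].duplicated().any():
            raise SecDiffError("duplicate sample_id in design matrix")

    @classmethod
    def read_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def sample_ids(self):
        return list(self.frame["sample_id"])

    @property
    def conditions(self):
        return list(pd.unique(self.frame["condition"]))

    def samples_for(self, condition):
        return list(self.frame.loc[self.frame["condition"] == condition, "sample_id"])

    def condition_of(self, sample_id):
        row = self.frame.loc[self.frame["sample_id"] == sample_id, "condition"]
        return row.iloc[0]

    def validate_against(self, traces):
        if set(self.sample_ids) != set(traces.sample_ids):
            raise SecDiffError("design matrix samples do not match trace samples")

    def write_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Molecular weight calibration
# ---------------------------------------------------------------------------

@dataclass
class FractionCalibration:
    """Log-linear map between SEC fraction index and apparent MW (kDa).

    Model: ``log10(MW) = slope * fraction_index + intercept`` with
    ``slope < 0`` (larger assemblies elute in earlier fractions).
    """

    slope: float
    intercept: float
    fit_points: list = field(default_factory=list)
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.slope >= 0:
            raise SecDiffError(
                "calibration slope must be negative (MW decreases with fraction)"
            )

    def fraction_to_mw(self, fraction):
        """Apparent molecular weight (kDa) at a (possibly fractional) fraction."""
        return 10.0 ** (self.slope * np.asarray(fraction, dtype=float) + self.intercept)

    def mw_to_fraction(self, mw):
        """Fraction index at which a given MW (kDa) elutes; may be fractional
        and outside the measured grid — clamping happens downstream."""
        mw = np.asarray(mw, dtype=float)
        if np.any(mw <= 0):
            raise SecDiffError("molecular weight must be positive")
        return (np.log10(mw) - self.intercept) / self.slope


def fit_calibration(standards):
    """Fit the log-linear calibration by OLS of log10(MW) on fraction index.

    Parameters
    ----------
    standards
        Iterable of ``(fraction_index, mw_kda)`` pairs from MW standards;
        at least two distinct fractions, all MW > 0.
    """
    pts = [(float(f), float(m)) for f, m in standards]
    if len(pts) < 2 or len({f for f, _ in pts}) < 2:
        raise SecDiffError("calibration needs >=2 standards at distinct fractions")
    if any(m <= 0 for _, m in pts):
        raise SecDiffError("standard molecular weights must be positive")
    x = np.array([f for f, _ in pts])
    y = np.log10([m for _, m in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return FractionCalibration(slope=float(slope), intercept=float(intercept),
                               fit_points=pts, r_squared=float(r2))


def read_calibration(path):
    """Read a calibration standards TSV (columns fraction_index, mw_kda) and fit."""
    df = pd.read_csv(path, sep="\t")
    return fit_calibration(zip(df["fraction_index"], df["mw_kda"]))


# ---------------------------------------------------------------------------
# Protein monomeric MW annotation
# ---------------------------------------------------------------------------

@dataclass
class ProteinMWAnnotation:
    """Monomeric molecular weights (kDa) keyed by protein accession."""

    mw: dict

    def __post_init__(self):
        bad = [p for p, m in self.mw.items() if not m > 0]
        if bad:
            raise SecDiffError(f"non-positive monomeric MW for {bad[:5]}")

    @classmethod
    def read_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["protein_id"], df["mw_kda"].astype(float))))

    def get(self, protein_id):
        return self.mw.get(protein_id)

    def write_tsv(self, path):
        pd.DataFrame(
            {"protein_id": list(self.mw), "mw_kda": list(self.mw.values())}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trace reading
# ---------------------------------------------------------------------------

def traces_from_long(df, fraction_max):
    """Build a :class:`PeptideTraceSet` from a long-format DataFrame.

    Fractions above ``fraction_max`` are dropped (late SEC fractions carry
    very low molecular weight material and are excluded from analysis); zero
    or absent intensities become missing; the grid is made contiguous
    ``1..fraction_max`` for every sample.
    """
    df = df.copy()
    missing_cols = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SecDiffError(f"trace table missing columns {missing_cols}")
    df["fraction_index"] = df["fraction_index"].astype(int)
    df = df[(df["fraction_index"] >= 1) & (df["fraction_index"] <= fraction_max)]

    dup = df.duplicated(["peptide_id", "sample_id", "fraction_index"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["peptide_id", "sample_id", "fraction_index"]]
            .drop_duplicates().head(10).to_dict("records")
        )
        raise SecDiffError(f"duplicate (peptide, sample, fraction) keys: {offenders}")

    pep2prot = df.groupby("peptide_id")["protein_id"].agg(lambda s: sorted(set(s)))
    ambiguous = pep2prot[pep2prot.str.len() > 1]
    if len(ambiguous):
        raise SecDiffError(
            "peptides mapped to multiple proteins: "
            + "; ".join(f"{p} -> {v}" for p, v in ambiguous.head(10).items())
        )

    peptide_ids = np.array(sorted(df["peptide_id"].unique()), dtype=object)
    sample_ids = sorted(df["sample_id"].unique())
    protein_ids = np.array([pep2prot[p][0] for p in peptide_ids], dtype=object)
    pidx = {p: i for i, p in enumerate(peptide_ids)}
    sidx = {s: i for i, s in enumerate(sample_ids)}

    data = np.full((len(peptide_ids), len(sample_ids), fraction_max), np.nan)
    rows = df[df["intensity"] > 0]
    data[
        [pidx[p] for p in rows["peptide_id"]],
        [sidx[s] for s in rows["sample_id"]],
        rows["fraction_index"].to_numpy() - 1,
    ] = rows["intensity"].to_numpy(dtype=float)
    return PeptideTraceSet(data, peptide_ids, protein_ids, sample_ids)


def read_traces(path, fraction_max=49):
    """Read a peptide trace TSV and truncate to fractions 1..``fraction_max``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return traces_from_long(df, fraction_max)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Global QC: per-entity CVs, sample correlation structure, coverage."""

    cv_within_condition: pd.DataFrame      # entity_id x condition
    cv_across_samples: pd.Series           # entity_id -> CV over all samples
    spearman: pd.DataFrame | None          # sample x sample correlation
    dendrogram_order: list | None          # sample ids in average-linkage leaf order
    fraction_counts: pd.DataFrame          # per sample x fraction peptide/protein counts


def _cv(values):
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2 or values.mean() == 0:
        return np.nan
    return values.std(ddof=1) / values.mean()


def _entity_sample_matrix(traces, design, features):
    """Entity x sample quantification matrix for QC.

    Uses protein SEC feature peak areas when features are supplied, else
    protein-level (or peptide-level) summed intensities across fractions.
    """
    if features:
        rows = {}
        for feat in features:
            areas = feat.peak_area or {}
            rows[f"{feat.owner_id}@{feat.apex_fraction}"] = {
                s: areas.get(s, np.nan) for s in design.sample_ids
            }
        return pd.DataFrame(rows).T.reindex(columns=design.sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sums = np.nansum(traces.data, axis=2)
    sums[np.all(np.isnan(traces.data), axis=2)] = np.nan
    if isinstance(traces, ProteinTraceSet):
        index = traces.protein_ids
    else:
        # aggregate peptides to their proteins
        frame = pd.DataFrame(sums, index=traces.peptide_ids, columns=traces.sample_ids)
        frame["__protein"] = traces.protein_ids
        agg = frame.groupby("__protein").sum(min_count=1)
        return agg.reindex(columns=design.sample_ids)
    return pd.DataFrame(sums, index=index, columns=traces.sample_ids).reindex(
        columns=design.sample_ids
    )


def qc_summary(traces, design, features=None):
    """Compute global QC statistics for an experiment.

    Per-entity coefficients of variation (CV) of quantities within each
    condition and across all samples, a sample x sample Spearman correlation
    matrix with an average-linkage dendrogram leaf order, and per-fraction
    peptide/protein detection counts.
    """
    design.validate_against(traces) if hasattr(traces, "peptide_ids") else None
    mat = _entity_sample_matrix(traces, design, features)

    cv_within = pd.DataFrame(index=mat.index)
    for cond in design.conditions:
        cols = design.samples_for(cond)
        cv_within[cond] = mat[cols].apply(_cv, axis=1)
    cv_across = mat.apply(_cv, axis=1)
    cv_across.name = "cv_all_samples"

    spearman = None
    order = None
    if len(design.sample_ids) >= 2:
        valid = mat.dropna()
        n_cols = mat.shape[1]
        if len(valid) < 2:
            logger.warning("fewer than 2 complete entities: sample "
                           "correlations undefined")
            rho = np.full((n_cols, n_cols), np.nan)
            np.fill_diagonal(rho, 1.0)
        else:
            rho = stats.spearmanr(valid.to_numpy(), axis=0)[0]
            rho = np.atleast_2d(rho)
            if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case
                r = stats.spearmanr(valid.iloc[:, 0], valid.iloc[:, 1])[0]
                rho = np.array([[1.0, r], [r, 1.0]])
        spearman = pd.DataFrame(rho, index=mat.columns, columns=mat.columns)
        if len(design.sample_ids) > 2 and np.isfinite(rho).all():
            dist = squareform(np.clip(1.0 - rho, 0, None), checks=False)
            order = [mat.columns[i] for i in leaves_list(linkage(dist, method="average"))]
        else:
            order = list(mat.columns)
    else:
        logger.warning("single sample: correlation matrix omitted from QC")

    counts = []
    if isinstance(traces, PeptideTraceSet):
        detected = np.isfinite(traces.data)
        for si, s in enumerate(traces.sample_ids):
            for fi in range(traces.n_fractions):
                mask = detected[:, si, fi]
                counts.append({
                    "sample_id": s, "fraction_index": fi + 1,
                    "n_peptides": int(mask.sum()),
                    "n_proteins": len(set(traces.protein_ids[mask])),
                })
    fraction_counts = pd.DataFrame(counts)
    return QCReport(cv_within, cv_across, spearman, order, fraction_counts)
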
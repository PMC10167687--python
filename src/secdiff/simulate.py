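"""Seeded generator of multi-condition SEC-MS datasets with ground truth.

The generator emulates the statistical structure the analysis assumes:
protein elution profiles are sums of Gaussian coelution peaks positioned by
apparent molecular weight through the log-linear fraction calibration
(monomers at their monomeric MW, assemblies at the complex MW), peptide
traces are the protein profile scaled by a per-peptide response factor with
multiplicative lognormal noise, and missingness combines a detection floor
with intensity-dependent dropout (probability logistic in -log2 intensity).
Condition effects enter as state-abundance differences: abundance fold
changes, assembled/monomer redistribution (AMF shifts), and feature-to-
feature redistribution at constant total (rewiring).

Everything is deterministic under the configured seed; regenerating with
the same seed reproduces identical data and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import (DesignMatrix, FractionCalibration, PeptideTraceSet,
                   ProteinMWAnnotation)
from .complexes import ComplexHypothesis


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """One elution state: a monomer or an assembly of one or more subunits.

    ``abundance`` maps condition -> peak amplitude contributed to every
    subunit's trace (stoichiometry 1 per subunit).
    """

    state_id: str
    subunits: tuple
    mw: float                      # apparent MW (kDa) positioning the peak
    abundance: dict

    def __post_init__(self):
        self.subunits = tuple(self.subunits)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated SEC-MS experiment.

    Defaults mirror a three-condition, three-replicate design over 49
    usable SEC fractions with a log-linear MW calibration spanning roughly
    1.4 MDa (fraction 1) down to 6 kDa (fraction 49).
    """

    protein_mmw: dict = field(default_factory=dict)   # protein -> MMW kDa
    states: list = field(default_factory=list)        # list[StateSpec]
    n_fractions: int = 49
    calibration_slope: float = -0.05
    calibration_intercept: float = 3.2
    conditions: tuple = ("c1", "c2", "c3")
    n_replicates: int = 3
    peptides_per_protein: tuple = (3, 6)              # inclusive range
    peak_sigma: float = 1.5                           # fractions
    response_sigma: float = 0.5                       # lognormal sigma of factors
    noise_cv: float = 0.1                             # multiplicative noise CV
    detection_limit: float = 1.0                      # intensities below -> missing
    dropout_scale: float = 0.0                        # max extra dropout probability
    dropout_midpoint: float = 10.0                    # intensity of half-max dropout
    dropout_steepness: float = 1.0                    # per log2-intensity unit
    seed: int = 0

    def calibration(self):
        return FractionCalibration(self.calibration_slope,
                                   self.calibration_intercept)

    def validate(self):
        cal = self.calibration()
        for st in self.states:
            for s in st.subunits:
                if s not in self.protein_mmw:
                    raise ValueError(f"state {st.state_id}: unknown protein {s}")
            if len(st.subunits) > 1:
                largest = max(self.protein_mmw[s] for s in st.subunits)
                if st.mw < largest:
                    raise ValueError(
                        f"state {st.state_id}: complex MW {st.mw} below the "
                        f"largest subunit MMW {largest}"
                    )
            f = float(cal.mw_to_fraction(st.mw))
            if not (0.0 <= f <= self.n_fractions + 1):
                raise ValueError(
                    f"state {st.state_id}: MW {st.mw} kDa elutes at fraction "
                    f"{f:.1f}, outside the calibrated grid"
                )


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset."""

    true_amf: pd.DataFrame          # protein x condition
    state_apex: dict                # state_id -> true apex fraction (float)
    state_log2fc: pd.DataFrame      # state x condition-pair log2 fold change
    protein_total_log2fc: pd.DataFrame  # protein x condition-pair
    dropout_mask: np.ndarray | None = None


@dataclass
class SimulatedDataset:
    traces: PeptideTraceSet
    design: DesignMatrix
    mw_annotation: ProteinMWAnnotation
    hypotheses: list
    truth: GroundTruth
    calibration: FractionCalibration


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------

def _gaussian(fractions, apex, sigma):
    return np.exp(-0.5 * ((fractions - apex) / sigma) ** 2)


def simulate(config, seed=None):
    """Generate a dataset and its ground truth from a configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cal = config.calibration()
    fractions = np.arange(1, config.n_fractions + 1, dtype=float)
    proteins = sorted(config.protein_mmw)

    # noiseless protein profile per condition
    state_apex = {st.state_id: float(cal.mw_to_fraction(st.mw))
                  for st in config.states}
    prot_profile = {
        p: {c: np.zeros(config.n_fractions) for c in config.conditions}
        for p in proteins
    }
    for st in config.states:
        peak = _gaussian(fractions, state_apex[st.state_id], config.peak_sigma)
        for c in config.conditions:
            amp = st.abundance.get(c, 0.0)
            for s in st.subunits:
                prot_profile[s][c] += amp * peak

    # design
    sample_ids, rows = [], []
    for c in config.conditions:
        for r in range(1, config.n_replicates + 1):
            sid = f"{c}_r{r}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "condition": c, "replicate": r})
    design = DesignMatrix(pd.DataFrame(rows))
    cond_of = {r["sample_id"]: r["condition"] for r in rows}

    # peptides
    lo, hi = config.peptides_per_protein
    pep_ids, prot_ids, factors = [], [], []
    for p in proteins:
        k = int(rng.integers(lo, hi + 1))
        f = rng.lognormal(mean=0.0, sigma=config.response_sigma, size=k)
        for i in range(k):
            pep_ids.append(f"{p}_pep{i + 1}")
            prot_ids.append(p)
            factors.append(f[i])
    factors = np.asarray(factors)

    n_pep, n_samp = len(pep_ids), len(sample_ids)
    data = np.empty((n_pep, n_samp, config.n_fractions))
    noise_sigma = np.sqrt(np.log1p(config.noise_cv**2))
    for si, sid in enumerate(sample_ids):
        c = cond_of[sid]
        base = np.vstack([prot_profile[pr][c] for pr in prot_ids]) * factors[:, None]
        if noise_sigma > 0:
            mult = rng.lognormal(mean=-0.5 * noise_sigma**2, sigma=noise_sigma,
                                 size=base.shape)
            base = base * mult
        data[:, si, :] = base

    # missingness: detection floor plus intensity-dependent dropout
    missing = data < config.detection_limit
    if config.dropout_scale > 0:
        with np.errstate(divide="ignore"):
            logi = np.where(data > 0, np.log2(data), -np.inf)
        p_miss = config.dropout_scale / (
            1.0 + np.exp(-config.dropout_steepness
                         * (np.log2(config.dropout_midpoint) - logi))
        )
        missing |= rng.random(data.shape) < p_miss
    data = np.where(missing, np.nan, data)

    traces = PeptideTraceSet(data, pep_ids, prot_ids, sample_ids)
    mw_annotation = ProteinMWAnnotation(dict(config.protein_mmw))
    hypotheses = [
        ComplexHypothesis(st.state_id, frozenset(st.subunits), source="custom")
        for st in config.states if len(st.subunits) >= 2
    ]
    truth = _ground_truth(config, cal, prot_profile, state_apex, missing)
    return SimulatedDataset(traces, design, mw_annotation, hypotheses, truth, cal)


def _ground_truth(config, cal, prot_profile, state_apex, dropout_mask):
    fractions = np.arange(1, config.n_fractions + 1)
    amf = {}
    for p, profiles in prot_profile.items():
        cutoff = np.clip(float(cal.mw_to_fraction(2.0 * config.protein_mmw[p])),
                         1.0, config.n_fractions)
        amf[p] = {}
        for c, y in profiles.items():
            total = y.sum()
            amf[p][c] = float(y[fractions < cutoff].sum() / total) if total > 0 \
                else np.nan
    true_amf = pd.DataFrame(amf).T.reindex(columns=list(config.conditions))

    pairs = list(combinations(config.conditions, 2))
    state_fc, prot_fc = {}, {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for st in config.states:
            state_fc[st.state_id] = {
                f"{a}/{b}": float(np.log2(st.abundance.get(a, 0.0)
                                          / st.abundance.get(b, 0.0)))
                if st.abundance.get(b, 0.0) > 0 else np.nan
                for a, b in pairs
            }
        for p, profiles in prot_profile.items():
            prot_fc[p] = {
                f"{a}/{b}": float(np.log2(profiles[a].sum() / profiles[b].sum()))
                if profiles[b].sum() > 0 else np.nan
                for a, b in pairs
            }
    return GroundTruth(
        true_amf=true_amf,
        state_apex=state_apex,
        state_log2fc=pd.DataFrame(state_fc).T,
        protein_total_log2fc=pd.DataFrame(prot_fc).T,
        dropout_mask=dropout_mask,
    )


def null_dataset(config, seed=None):
    """Simulate with every condition effect removed (truth marks all null).

    All state abundances are replaced by their value in the first
    condition, so between-condition differences arise from noise alone.
    """
    from dataclasses import replace
    ref = config.conditions[0]
    states = [
        StateSpec(st.state_id, st.subunits, st.mw,
                  {c: st.abundance.get(ref, 0.0) for c in config.conditions})
        for st in config.states
    ]
    return simulate(replace(config, states=states), seed=seed)


# ---------------------------------------------------------------------------
# Study-condition builders
# ---------------------------------------------------------------------------

def amf_shift_cohort(n_proteins=1000, n_shifted=50, shift=0.4,
                     conditions=("A", "B"), n_replicates=3, noise_cv=0.1,
                     seed=0):
    """Cohort of monomer+self-assembly proteins, a subset shifting AMF.

    Each protein carries a monomer peak at its MMW and an assembled peak at
    four times its MMW; baseline assembled share is drawn uniformly from
    [0.15, 0.45] and the first ``n_shifted`` proteins gain ``shift`` of
    assembled share in the second condition at constant total abundance.
    Returns ``(config, shifted_protein_ids)``.
    """
    rng = np.random.default_rng(seed)
    mmw = {f"P{i:04d}": float(rng.uniform(20, 120)) for i in range(n_proteins)}
    states = []
    shifted = []
    for i, (p, m) in enumerate(sorted(mmw.items())):
        total = float(rng.lognormal(np.log(2000), 0.3))
        base = float(rng.uniform(0.15, 0.45))
        fracs = {c: base for c in conditions}
        if i < n_shifted:
            fracs[conditions[1]] = base + shift
            shifted.append(p)
        states.append(StateSpec(f"{p}_asm", (p,), 4.0 * m,
                                {c: total * fracs[c] for c in conditions}))
        states.append(StateSpec(f"{p}_mono", (p,), m,
                                {c: total * (1.0 - fracs[c]) for c in conditions}))
    config = SimulationConfig(
        protein_mmw=mmw, states=states, conditions=tuple(conditions),
        n_replicates=n_replicates, noise_cv=noise_cv, seed=seed,
    )
    return config, shifted


def abundance_fc_cohort(n_proteins=50, log2fc=2.0, n_changed=None,
                        conditions=("A", "B"), n_replicates=3, noise_cv=0.1,
                        seed=0):
    """Single-state proteins with a planted abundance fold change.

    Every protein elutes as one assembled peak; the first ``n_changed``
    (default: all) are ``2**log2fc``-fold more abundant in the first
    condition.  Returns ``(config, changed_protein_ids)``.
    """
    rng = np.random.default_rng(seed)
    n_changed = n_proteins if n_changed is None else n_changed
    mmw = {f"Q{i:04d}": float(rng.uniform(30, 100)) for i in range(n_proteins)}
    states, changed = [], []
    for i, (p, m) in enumerate(sorted(mmw.items())):
        base = float(rng.lognormal(np.log(2000), 0.3))
        ab = {c: base for c in conditions}
        if i < n_changed:
            ab[conditions[0]] = base * 2.0**log2fc
            changed.append(p)
        states.append(StateSpec(f"{p}_asm", (p,), 4.0 * m, ab))
    config = SimulationConfig(
        protein_mmw=mmw, states=states, conditions=tuple(conditions),
        n_replicates=n_replicates, noise_cv=noise_cv, seed=seed,
    )
    return config, changed


def complex_benchmark(n_real=50, n_null=450, subunits_per_complex=3,
                      conditions=("A", "B"), n_replicates=3, noise_cv=0.1,
                      seed=0):
    """Planted-complex benchmark: real coeluting complexes plus null queries.

    ``n_real`` complexes of coeluting subunits are planted; ``n_null``
    additional hypotheses group random monomer-only proteins that share no
    true complex, providing known-false queries for FDR calibration.
    Returns ``(config, hypotheses, real_ids, null_ids)``.
    """
    rng = np.random.default_rng(seed)
    n_complex_prot = n_real * subunits_per_complex
    n_free = max(subunits_per_complex * 4, 40)
    proteins = [f"C{i:04d}" for i in range(n_complex_prot + n_free)]
    mmw = {p: float(rng.uniform(30, 70)) for p in proteins}

    states, hypotheses, real_ids = [], [], []
    for k in range(n_real):
        subs = tuple(proteins[k * subunits_per_complex:(k + 1) * subunits_per_complex])
        cmw = 1.2 * sum(mmw[s] for s in subs)
        total = float(rng.lognormal(np.log(3000), 0.3))
        cid = f"CPX{k:03d}"
        real_ids.append(cid)
        states.append(StateSpec(cid, subs, cmw, {c: total for c in conditions}))
        for s in subs:  # modest monomeric share per subunit
            states.append(StateSpec(f"{s}_mono", (s,), mmw[s],
                                    {c: 0.4 * total for c in conditions}))
        hypotheses.append(ComplexHypothesis(cid, frozenset(subs), source="custom"))
    free = proteins[n_complex_prot:]
    for p in free:
        total = float(rng.lognormal(np.log(3000), 0.3))
        states.append(StateSpec(f"{p}_mono", (p,), mmw[p],
                                {c: total for c in conditions}))
    null_ids = []
    for k in range(n_null):
        subs = tuple(rng.choice(free, size=subunits_per_complex, replace=False))
        cid = f"NULL{k:03d}"
        null_ids.append(cid)
        hypotheses.append(ComplexHypothesis(cid, frozenset(subs), source="custom"))
    config = SimulationConfig(
        protein_mmw=mmw, states=states, conditions=tuple(conditions),
        n_replicates=n_replicates, noise_cv=noise_cv, seed=seed,
    )
    return config, hypotheses, real_ids, null_ids


def redistribution_fixture(conditions=("A", "B"), n_replicates=3,
                           noise_cv=0.0, seed=0):
    """A protein redistributing mass between two assembly states.

    Total abundance stays constant while 80% of the mass sits in the
    high-MW state in the first condition and in the low-MW state in the
    second — the signature of rewiring: feature-level and FMF changes with
    no global abundance change.  Returns ``(config, protein_id)``.
    """
    mmw = {"RW01": 50.0}
    total = 5000.0
    states = [
        StateSpec("RW01_big", ("RW01",), 800.0,
                  {conditions[0]: 0.8 * total, conditions[1]: 0.2 * total}),
        StateSpec("RW01_small", ("RW01",), 120.0,
                  {conditions[0]: 0.2 * total, conditions[1]: 0.8 * total}),
    ]
    config = SimulationConfig(
        protein_mmw=mmw, states=states, conditions=tuple(conditions),
        n_replicates=n_replicates, noise_cv=noise_cv,
        peptides_per_protein=(4, 4), seed=seed,
    )
    return config, "RW01"
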
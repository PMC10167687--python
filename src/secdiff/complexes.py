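"""Hypothesis-driven protein complex detection and differential analysis.

Prior connectivity knowledge (CORUM-style complex rosters or clustered PPI
networks) supplies complex hypotheses; the SEC data are queried directly
for coeluting subunit groups.  Error rates are controlled with randomized
decoy hypotheses whose member pairs are far apart in the PPI graph
(minimum edge distance), only the most complete feature per query enters
FDR estimation, features at implausibly low apparent MW (at or below twice
the largest subunit monomer) are discarded, confident queries are appended
with high-correlation secondary features, redundant features across
queries are collapsed, and complex-level differential statistics are
aggregated up from peptide-level tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .differential import (DifferentialResult, aggregate_to_parent,
                           feature_differential)
from .features import (FeatureFinderParams, estimate_q_values, find_features,
                       integrate_traces)

logger = logging.getLogger("secdiff")


@dataclass
class ComplexHypothesis:
    """A queried complex: an identifier and a set of subunit accessions."""

    complex_id: str
    subunits: frozenset
    source: str = "custom"   # corum | string_cluster | custom | decoy
    relaxed_decoy: bool = False

    def __post_init__(self):
        self.subunits = frozenset(self.subunits)
        if len(self.subunits) < 2:
            raise ValueError(f"complex {self.complex_id} has <2 subunits")

    @property
    def is_decoy(self):
        return self.source == "decoy"


def read_hypotheses(path, source="custom"):
    """Read complex hypotheses from a membership TSV (complex_id, protein_id).

    Duplicate membership rows are deduplicated; hypotheses reduced to a
    single subunit are dropped with a warning.  Subunits absent from the
    trace data are retained for completeness accounting.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, grp in df.groupby("complex_id", sort=True):
        subs = set(grp["protein_id"])
        if len(subs) < 2:
            logger.warning("complex %s has <2 subunits; dropped", cid)
            continue
        out.append(ComplexHypothesis(str(cid), frozenset(subs), source=source))
    return out


def read_ppi_edges(path):
    """Read a PPI edge TSV (protein_a, protein_b[, combined_score])."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(zip(df["protein_a"], df["protein_b"]))
    return g


# ---------------------------------------------------------------------------
# Decoy hypotheses
# ---------------------------------------------------------------------------

def make_complex_decoys(hypotheses, ppi_graph=None, min_edge_distance=3,
                        seed=0, max_tries=200):
    """Random decoy hypotheses, one per target, of matched size.

    Every pair of decoy members must lie at shortest-path distance >=
    ``min_edge_distance`` in the PPI graph (nodes absent from the graph are
    treated as infinitely distant).  Without a graph the constraint
    degrades to "no shared target-complex membership".  Rejection sampling
    runs under a bounded retry budget; on exhaustion a relaxed decoy is
    emitted and flagged.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set().union(*(h.subunits for h in hypotheses)))
    if ppi_graph is not None:
        dist_ok = _make_graph_distance_check(ppi_graph, min_edge_distance)
    else:
        logger.info("no PPI edges supplied: decoy constraint degrades to "
                    "no shared complex membership")
        comembers = {}
        for h in hypotheses:
            for s in h.subunits:
                comembers.setdefault(s, set()).update(h.subunits)

        def dist_ok(a, b):
            return b not in comembers.get(a, ())

    decoys = []
    for h in sorted(hypotheses, key=lambda x: x.complex_id):
        k = len(h.subunits)
        chosen = None
        for _ in range(max_tries):
            cand = list(rng.choice(universe, size=k, replace=False))
            if all(dist_ok(a, b) for i, a in enumerate(cand) for b in cand[i + 1:]):
                chosen = cand
                break
        relaxed = chosen is None
        if relaxed:
            logger.warning("decoy for %s: retry budget exhausted, relaxed "
                           "distance constraint", h.complex_id)
            chosen = list(rng.choice(universe, size=k, replace=False))
        decoys.append(ComplexHypothesis(
            f"DECOY_{h.complex_id}", frozenset(chosen), source="decoy",
        ))
        decoys[-1].relaxed_decoy = relaxed
    return decoys


def _make_graph_distance_check(graph, min_dist):
    cache = {}

    def ok(a, b):
        if a not in graph or b not in graph:
            return True
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            try:
                d = nx.shortest_path_length(graph, key[0], key[1])
            except nx.NetworkXNoPath:
                d = np.inf
            cache[key] = d
        return cache[key] >= min_dist

    return ok


# ---------------------------------------------------------------------------
# Complex feature detection
# ---------------------------------------------------------------------------

def detect_complex_features(hypotheses, decoys, protein_traces, params=None,
                            calibration=None, mw_annotation=None, fdr=0.05,
                            secondary_corr=0.7):
    """Complex-centric feature detection with target-decoy FDR control.

    Per query: coelution features are found over the subunits' integrated
    traces; features whose apex MW does not exceed twice the largest
    subunit monomeric MW are discarded; the most complete feature (ties:
    higher coelution score, then earlier apex) is the primary used for
    scoring.  q-values are estimated over all primaries against the decoy
    primaries on the composite (completeness, score) rank; target queries
    with q <= ``fdr`` keep their primary plus any other feature with
    coelution score >= ``secondary_corr`` as secondary features.

    Returns ``(accepted_features, target_primaries, decoy_primaries,
    n_skipped_queries)``.
    """
    params = params or FeatureFinderParams(collapse_method="apex_network")
    integrated = integrate_traces(protein_traces)
    available = set(integrated)

    def query_features(hyp):
        present = sorted(hyp.subunits & available)
        if len(present) < 2:
            return None
        traces = {p: integrated[p] for p in present}
        feats = find_features(
            traces, params, calibration, owner_id=hyp.complex_id,
            n_queried=len(hyp.subunits), is_decoy=hyp.is_decoy,
        )
        if mw_annotation is not None and calibration is not None:
            max_mmw = max(
                (mw_annotation.get(p) or 0.0) for p in hyp.subunits
            )
            feats = [f for f in feats if f.apex_mw > 2.0 * max_mmw]
        return feats

    n_skipped = 0
    target_primary, decoy_primary, extras = [], [], {}
    for hyp in hypotheses:
        feats = query_features(hyp)
        if feats is None:
            n_skipped += 1
            continue
        if not feats:
            continue
        feats.sort(key=lambda f: (-len(f.member_ids), -f.coelution_score,
                                  f.apex_fraction))
        target_primary.append(feats[0])
        extras[hyp.complex_id] = feats[1:]
    for hyp in decoys:
        feats = query_features(hyp)
        if not feats:
            continue
        feats.sort(key=lambda f: (-len(f.member_ids), -f.coelution_score,
                                  f.apex_fraction))
        decoy_primary.append(feats[0])

    if decoy_primary:
        estimate_q_values(
            target_primary, decoy_primary,
            key=lambda f: (f.completeness, f.coelution_score),
        )
    else:
        for f in target_primary:
            f.q_value = 0.0
            f.p_value = 1.0 / (len(decoy_primary) + 1)

    accepted = []
    for f in target_primary:
        if f.q_value <= fdr:
            accepted.append(f)
            for sec in extras.get(f.owner_id, []):
                if sec.coelution_score >= secondary_corr:
                    sec.is_secondary = True
                    sec.q_value = f.q_value
                    accepted.append(sec)
    return accepted, target_primary, decoy_primary, n_skipped


def completeness_class(feature):
    """Detection completeness class: full / >=50% / <50% of queried subunits."""
    if feature.completeness >= 1.0:
        return "full"
    if feature.completeness >= 0.5:
        return ">=50%"
    return "<50%"


# ---------------------------------------------------------------------------
# Redundancy collapsing
# ---------------------------------------------------------------------------

def collapse_features(features, rt_height=0.0, distance_cutoff=1.25):
    """Collapse redundant complex features across queries.

    Features are grouped by single linkage: two features link when their
    apex distance is at most ``distance_cutoff`` fractions AND their
    subunit sets overlap (Jaccard > 0).  Each group is reduced to one
    representative — largest subunit set, ties broken by higher coelution
    score.  ``rt_height = 0`` means no extra peak-merging tolerance beyond
    the apex-distance clustering.  Returns ``(representatives, mapping)``
    where mapping sends each input feature index to its representative.
    """
    n = len(features)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    tol = distance_cutoff + rt_height
    for i in range(n):
        for j in range(i + 1, n):
            fi, fj = features[i], features[j]
            if abs(fi.apex_fraction - fj.apex_fraction) <= tol and \
                    set(fi.member_ids) & set(fj.member_ids):
                union(i, j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    reps, mapping = [], {}
    for members in groups.values():
        rep = min(members, key=lambda k: (-len(features[k].member_ids),
                                          -features[k].coelution_score))
        reps.append(features[rep])
        for k in members:
            mapping[k] = rep
    reps.sort(key=lambda f: (f.apex_fraction, f.owner_id))
    return reps, mapping


# ---------------------------------------------------------------------------
# Complex-level differential analysis
# ---------------------------------------------------------------------------

def complex_differential(features, peptide_traces, design, condition_a,
                         condition_b, hypotheses=None, rng=None,
                         log2fc_min=1.0, alpha=0.05):
    """Differential statistics per complex feature.

    Within each complex feature's boundary range, peptide-level tests are
    run and aggregated per subunit protein, then protein-level statistics
    are aggregated once more to the complex; BH correction runs across
    complexes and significance requires ``|log2FC| >= log2fc_min`` and
    adjusted p <= ``alpha``.
    """
    from dataclasses import replace
    rng = rng if rng is not None else np.random.default_rng(0)
    pep_of_protein = {}
    for pep, prot in zip(peptide_traces.peptide_ids, peptide_traces.protein_ids):
        pep_of_protein.setdefault(prot, []).append(pep)

    results = []
    for feat in features:
        prot_fcs, prot_ps = [], []
        n_members = 0
        for prot in feat.member_ids:
            peps = pep_of_protein.get(prot)
            if not peps:
                continue
            pf = replace(feat, owner_id=prot, member_ids=list(peps))
            r = feature_differential(
                pf, peptide_traces, design, condition_a, condition_b, rng=rng,
            )
            if np.isfinite(r.log2fc) and np.isfinite(r.p_value):
                prot_fcs.append(r.log2fc)
                prot_ps.append(r.p_value)
                n_members += 1
        res = DifferentialResult(entity_id=feat.owner_id, level="complex")
        if not prot_fcs:
            res.flags.append("no_subunit_peptide_data")
            logger.info("complex %s: no subunit peptide data; omitted",
                        feat.owner_id)
        else:
            fc, p = aggregate_to_parent(prot_fcs, prot_ps)
            res.log2fc, res.p_value = fc, p
            res.n_members_aggregated = n_members
        results.append(res)

    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        from .amf import bh_adjust
        adj = bh_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)
            r.significant = (
                np.isfinite(r.log2fc) and abs(r.log2fc) >= log2fc_min
                and r.adjusted_p <= alpha
            )
    return [r for r in results if "no_subunit_peptide_data" not in r.flags]
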
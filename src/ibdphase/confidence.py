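"""Phase-confidence estimation.

A minority of probands end up phased poorly genome-wide (superclusters
oriented wrong, or too little IBD).  Features of the finished run — how
often individuals ended up with segments on both parental sides, how
much of the genome the IBD covers, how connected the close family is —
are fed to a regression model (random forest by default) that predicts
the genome-wide phase error.  When the predicted error exceeds 20% the
confident labeling falls back from the largest supercluster to the
largest subcluster.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .cluster import Subcluster, Supercluster, largest_supercluster

RATIO_CAP = 100.0  # cap for degenerate ratios (empty denominator)
FALLBACK_THRESHOLD = 0.20


@dataclass
class ConfidenceFeatures:
    frac_both_sides_largest_sc: float = 0.0
    frac_split_segments: float = 0.0
    n_inconsistent_close_family: float = 0.0
    log_n_ibd_individuals: float = 0.0
    log_n_segments_largest_sc: float = 0.0
    n_missing_family_edges: float = 0.0
    coverage_1x: float = 0.0
    coverage_2x: float = 0.0
    coverage_5x: float = 0.0
    coverage_10x: float = 0.0
    coverage_20x: float = 0.0
    single_vs_multi_ratio: float = 0.0
    frac_segments_largest_sc: float = 0.0
    majority_minority_ratio_mean: float = 0.0
    majority_minority_ratio_median: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def genome_coverage_fractions(segments, sites, ks=(1, 2, 5, 10, 20)) -> dict[int, float]:
    """Fraction of genome (in cM) overlapped by at least k segments."""
    cov = np.zeros(sites.n_sites, dtype=np.int32)
    for s in segments:
        cov[s.start:s.end] += 1
    total = sites.genome_cm()
    out = {k: 0.0 for k in ks}
    if total <= 0:
        return out
    for _c, sl in sites.chrom_slices().items():
        gaps = np.diff(sites.cm[sl])
        c = cov[sl][:-1]
        for k in ks:
            out[k] += float(gaps[c >= k].sum())
    return {k: v / total for k, v in out.items()}


def extract_features(run) -> ConfidenceFeatures:
    """Build the feature vector from a completed run.

    ``run`` must expose: segments, stats (per-individual RelationshipStats),
    family (CloseFamilyGraph or None), assignment, subclusters,
    superclusters, fragment_sides, and sites.  Missing upstream artifacts
    raise an error naming the stage.
    """
    for stage in ("segments", "assignment", "subclusters", "superclusters", "sites"):
        if getattr(run, stage, None) is None:
            raise ValueError(f"missing upstream artifact: {stage}")
    f = ConfidenceFeatures()
    segments = run.segments
    n_indiv = len({s.other_id for s in segments})
    f.log_n_ibd_individuals = float(np.log1p(n_indiv))

    cov = genome_coverage_fractions(segments, run.sites)
    f.coverage_1x, f.coverage_2x, f.coverage_5x = cov[1], cov[2], cov[5]
    f.coverage_10x, f.coverage_20x = cov[10], cov[20]

    per_indiv_segs: dict[str, int] = {}
    for s in segments:
        per_indiv_segs[s.other_id] = per_indiv_segs.get(s.other_id, 0) + 1
    n_single = sum(1 for v in per_indiv_segs.values() if v == 1)
    n_multi = sum(1 for v in per_indiv_segs.values() if v > 1)
    if n_multi:
        f.single_vs_multi_ratio = n_single / n_multi
    elif n_single:
        f.single_vs_multi_ratio = RATIO_CAP

    if run.family is not None:
        nodes = run.family.nodes
        for m in nodes:
            if any(not run.family.graph.has_edge(m, n) for n in nodes if n != m):
                f.n_inconsistent_close_family += 1
        f.n_missing_family_edges = float(run.family.missing_edges())

    frag_by_id = {fr.id: fr for fr in run.assignment.fragments}
    sides = run.fragment_sides or {}
    # split segments: fragments on both global sides
    seg_sides: dict[int, set] = {}
    for fr in run.assignment.fragments:
        seg_sides.setdefault(fr.seg_id, set()).add(sides.get(fr.id, fr.side))
    if segments:
        f.frac_split_segments = sum(1 for v in seg_sides.values() if len(v) == 2) / len(segments)

    big = largest_supercluster(run.superclusters, run.subclusters)
    if big is not None:
        members = set(big.pruned_members or big.members)
        seg_ids: set[int] = set()
        indiv_sides: dict[str, set] = {}
        for sc in run.subclusters:
            if sc.id not in members:
                continue
            for fid, _side in sc.members:
                fr = frag_by_id[fid]
                seg_ids.add(fr.seg_id)
                indiv_sides.setdefault(fr.other_id, set()).add(sides.get(fid, fr.side))
        f.log_n_segments_largest_sc = float(np.log1p(len(seg_ids)))
        if segments:
            f.frac_segments_largest_sc = len(seg_ids) / len(segments)
        if indiv_sides:
            f.frac_both_sides_largest_sc = (
                sum(1 for v in indiv_sides.values() if len(v) == 2) / len(indiv_sides))

    # majority/minority side ratio per database individual (cM-weighted)
    indiv_cm: dict[str, list[float]] = {}
    for fr in run.assignment.fragments:
        d = indiv_cm.setdefault(fr.other_id, [0.0, 0.0])
        d[sides.get(fr.id, fr.side)] += fr.cm
    ratios = []
    for a, b in indiv_cm.values():
        lo, hi = min(a, b), max(a, b)
        ratios.append(hi / lo if lo > 0 else RATIO_CAP)
    if ratios:
        f.majority_minority_ratio_mean = float(np.mean(ratios))
        f.majority_minority_ratio_median = float(np.median(ratios))
    return f


class ErrorModel:
    """Pluggable regressor predicting genome-wide phase error from run features."""

    def __init__(self, regressor=None, seed: int = 0):
        if regressor is None:
            from sklearn.ensemble import RandomForestRegressor
            regressor = RandomForestRegressor(n_estimators=200, random_state=seed)
        self.regressor = regressor
        self.feature_names = ConfidenceFeatures.names()

    def fit(self, X, y) -> "ErrorModel":
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("label/feature length mismatch")
        self.regressor.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.regressor.predict(_as_matrix(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        return getattr(self.regressor, "feature_importances_", None)

    def save(self, path) -> None:
        import joblib
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ErrorModel":
        import joblib
        return joblib.load(path)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ConfidenceFeatures):
        return X.to_array()[None, :]
    X = list(X) if not isinstance(X, np.ndarray) else X
    if len(X) and isinstance(X[0], ConfidenceFeatures):
        return np.stack([x.to_array() for x in X])
    return np.atleast_2d(np.asarray(X, dtype=float))


def fit_error_model(features, errors, regressor=None, seed: int = 0) -> ErrorModel:
    """Fit the error regressor on labeled runs (features -> observed error)."""
    return ErrorModel(regressor, seed).fit(features, errors)


def apply_confidence_fallback(prediction: float, subclusters: list[Subcluster],
                              superclusters: list[Supercluster]
                              ) -> tuple[str, list[int]]:
    """Conservative labeling: above 20% predicted error (strictly), restrict
    the confident labeling to the largest subcluster instead of the largest
    supercluster."""
    big_sup = largest_supercluster(superclusters, subclusters)
    if prediction > FALLBACK_THRESHOLD:
        if not subclusters:
            return "subcluster", []
        big_sub = max(subclusters, key=lambda s: (len(s.members), -s.id))
        return "subcluster", [big_sub.id]
    if big_sup is None:
        return "supercluster", []
    return "supercluster", list(big_sup.pruned_members or big_sup.members)


def synthetic_feature_table(n_runs: int, rng: np.random.Generator
                            ) -> list[ConfidenceFeatures]:
    """Synthetic feature rows spanning sparse-to-dense IBD regimes.

    A stand-in for large collections of labeled pipeline runs, used to
    exercise the regressor (planted-signal and null checks) without
    simulating thousands of genomes.
    """
    rows = []
    for _ in range(n_runs):
        density = rng.uniform(0, 1)
        c1 = min(1.0, density * rng.uniform(0.8, 1.4))
        f = ConfidenceFeatures(
            frac_both_sides_largest_sc=rng.beta(1.2, 8) * (1.2 - density),
            frac_split_segments=rng.beta(1.2, 12),
            n_inconsistent_close_family=float(rng.poisson(2)),
            log_n_ibd_individuals=np.log1p(rng.uniform(5, 400) * (0.3 + density)),
            log_n_segments_largest_sc=np.log1p(rng.uniform(3, 300) * density),
            n_missing_family_edges=float(rng.poisson(3)),
            coverage_1x=c1,
            coverage_2x=c1 * rng.uniform(0.6, 1.0),
            coverage_5x=c1 * rng.uniform(0.2, 0.7),
            coverage_10x=c1 * rng.uniform(0.05, 0.4),
            coverage_20x=c1 * rng.uniform(0.0, 0.2),
            single_vs_multi_ratio=rng.uniform(0.2, 8.0),
            frac_segments_largest_sc=rng.beta(4, 2) * density + rng.beta(1.5, 6) * (1 - density),
            majority_minority_ratio_mean=rng.uniform(1, 40),
            majority_minority_ratio_median=rng.uniform(1, 40),
        )
        rows.append(f)
    return rows
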
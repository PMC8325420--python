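"""Centre-level multivariate anomaly detection.

Each centre is summarised by a feature vector over the monitored
variable panel (continuous variables as centre means, binary ones as
centre proportions).  Features are standardised across centres, a
common covariance is estimated with optional shrinkage towards its
diagonal, and each centre's Mahalanobis distance from the common mean
is computed.  The sampling error of each centre's own summary is then
quantified by bootstrap (Monte-Carlo) resampling of that centre's
participants — 10,000 resamples by default — holding the common model
fixed.  A centre is flagged *suspected* when the median resampled
distance lies outside the limit, and *confirmed* when even the 5%
quantile does, i.e. the centre stays outside the limit after allowing
for its own sampling error.

The scalar limit (default 2 standard deviations) is converted to the
p-dimensional radius enclosing the same probability mass as the
two-sided +/-2-SD interval does in one dimension, so "outside 2 SD"
means the same thing whatever the panel size; at p=1 the radius is
exactly the threshold.

Exclusion rules: centres with fewer than 5 participants are excluded,
and a variable is dropped when any included centre has fewer than 5
entries of it, so that all centres share one feature space.  The
restricted allocation field is never read — the analysis is blinded to
group allocation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import (ConfigError, DegenerateModelError,
                     InsufficientCentresError)
from .trial_model import MonitoringConfig, TrialDataset

QUANTS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class CentreFeatureMatrix:
    centre_ids: list[str]
    feature_names: list[str]
    values: np.ndarray                       # centre x feature
    n_participants: dict[str, int]
    excluded_centres: list[tuple[str, str]]  # (centre_id, reason)
    excluded_features: list[tuple[str, str]]
    participant_values: dict[str, np.ndarray] = field(repr=False,
                                                      default_factory=dict)


@dataclass
class CommonModel:
    feature_names: list[str]
    location: np.ndarray                 # per-feature across-centre mean
    scale: np.ndarray                    # per-feature across-centre SD
    covariance: np.ndarray               # shrunk, on the standardised scale
    shrinkage_used: float
    dropped_features: list[tuple[str, str]]
    feature_index: np.ndarray            # columns kept from the matrix
    _chol: np.ndarray = field(repr=False, default=None)

    def standardise(self, vectors: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(vectors)[:, self.feature_index]
                - self.location) / self.scale


@dataclass
class DistanceDistribution:
    centre_id: str
    observed: float
    distances: np.ndarray                # resampled distances
    n_resamples: int
    seed: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.distances, q))

    @property
    def median(self) -> float:
        return self.quantile(0.50)

    @property
    def q05(self) -> float:
        return self.quantile(0.05)


@dataclass(frozen=True)
class CentreFlag:
    centre_id: str
    tier: str                            # none / suspected / confirmed
    observed: float
    median_resampled: float
    q05_resampled: float
    threshold: float                     # the scalar SD limit
    radius: float                        # its p-dimensional equivalent


# --------------------------------------------------------------------------
# feature matrix


def _numeric_panel(dataset: TrialDataset) -> pd.DataFrame:
    """Participant x feature numeric table over the monitored panel.

    Binary variables become 0/1 indicators of their positive level;
    categorical ones expand to one indicator per non-reference level.
    """
    wide = dataset.wide_values()
    cols: dict[str, pd.Series] = {}
    for v in dataset.dictionary:
        if not v.monitored:
            continue
        raw = (wide[v.name] if v.name in wide.columns
               else pd.Series(np.nan, index=wide.index, dtype=object))
        if v.kind == "continuous":
            cols[v.name] = pd.to_numeric(raw, errors="coerce")
        elif v.kind == "binary":
            out = pd.Series(np.nan, index=wide.index)
            out[raw.notna()] = (raw[raw.notna()] == v.positive_level) * 1.0
            cols[v.name] = out
        else:
            for level in v.levels[1:]:
                out = pd.Series(np.nan, index=wide.index)
                out[raw.notna()] = (raw[raw.notna()] == level) * 1.0
                cols[f"{v.name}={level}"] = out
    panel = pd.DataFrame(cols, index=wide.index)
    # participants with no values at all still belong to their centre
    missing = dataset.participants.loc[
        ~dataset.participants["participant_id"].isin(panel.index),
        "participant_id"]
    if len(missing):
        panel = pd.concat([panel, pd.DataFrame(
            np.nan, index=pd.Index(missing), columns=panel.columns)])
    return panel


def build_centre_features(dataset: TrialDataset,
                          config: MonitoringConfig | None = None
                          ) -> CentreFeatureMatrix:
    """Centre x feature summary matrix with the exclusion rules applied.

    Centres below ``min_participants_per_centre`` are excluded (reason
    "small_centre"); a feature is excluded when any included centre has
    fewer than ``min_entries_per_variable`` non-missing entries of it
    (reason "sparse_feature"), keeping one shared feature space.
    Remaining missing values are mean-imputed within centre.
    """
    config = config or MonitoringConfig()
    panel = _numeric_panel(dataset)
    centre_of = dataset.participants.set_index("participant_id")["centre_id"]
    sizes = centre_of.value_counts()

    excluded_centres = [(c, "small_centre") for c in sorted(sizes.index)
                        if sizes[c] < config.min_participants_per_centre]
    included = [c for c in sorted(sizes.index)
                if sizes[c] >= config.min_participants_per_centre]
    if len(included) < 3:
        raise InsufficientCentresError(
            f"only {len(included)} centre(s) pass the "
            f">={config.min_participants_per_centre}-participant rule; "
            "a common mean needs at least 3")

    groups = {c: panel.loc[centre_of[centre_of == c].index] for c in included}
    excluded_features: list[tuple[str, str]] = []
    kept: list[str] = []
    for name in panel.columns:
        counts = [groups[c][name].notna().sum() for c in included]
        if min(counts) < config.min_entries_per_variable:
            excluded_features.append((name, "sparse_feature"))
        else:
            kept.append(name)
    if not kept:
        raise DegenerateModelError("no feature passes the entries rule")

    rows, pvals = [], {}
    for c in included:
        g = groups[c][kept]
        means = g.mean()
        rows.append(means.to_numpy(dtype=float))
        pvals[c] = g.fillna(means).to_numpy(dtype=float)

    return CentreFeatureMatrix(
        centre_ids=included, feature_names=kept,
        values=np.vstack(rows),
        n_participants={c: int(sizes[c]) for c in included},
        excluded_centres=excluded_centres,
        excluded_features=excluded_features,
        participant_values=pvals)


# --------------------------------------------------------------------------
# common model


def fit_common_model(features: CentreFeatureMatrix,
                     config: MonitoringConfig | None = None) -> CommonModel:
    """Standardise features across centres and estimate the shrunk
    covariance Sigma* = (1-lambda) S + lambda diag(S).

    Scale is the across-centre standard deviation, so proportions and
    means live on one scale; zero-variance features are dropped with a
    logged reason.  "auto" uses the Ledoit-Wolf shrinkage intensity
    (whose target coincides with diag(S) = I on the standardised scale),
    which grows with p/n and keeps Sigma* well conditioned even when the
    panel is wider than the number of centres; lambda=1 gives the
    identity, hence positive definiteness is always reachable.
    """
    config = config or MonitoringConfig()
    X = features.values
    loc_all = X.mean(axis=0)
    scale_all = X.std(axis=0, ddof=1)
    keep = scale_all > 1e-12
    dropped = [(features.feature_names[j], "zero_variance")
               for j in np.flatnonzero(~keep)]
    if not keep.any():
        raise DegenerateModelError("all features have zero across-centre "
                                   "variance")
    idx = np.flatnonzero(keep)
    loc, scale = loc_all[idx], scale_all[idx]
    Z = (X[:, idx] - loc) / scale
    S = np.atleast_2d(np.cov(Z, rowvar=False, ddof=1))

    diag = np.diag(np.diag(S))
    if config.covariance_shrinkage == "auto":
        from sklearn.covariance import ledoit_wolf_shrinkage
        lam = float(ledoit_wolf_shrinkage(Z - Z.mean(axis=0),
                                          assume_centered=True))
    else:
        lam = float(config.covariance_shrinkage)
    sigma = (1 - lam) * S + lam * diag
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError(
            f"covariance not positive definite at shrinkage {lam}; "
            "increase covariance_shrinkage or use 'auto'") from exc

    return CommonModel(
        feature_names=[features.feature_names[j] for j in idx],
        location=loc, scale=scale, covariance=sigma, shrinkage_used=lam,
        dropped_features=dropped, feature_index=idx, _chol=chol)


def _distances(model: CommonModel, Z: np.ndarray) -> np.ndarray:
    return np.linalg.norm(
        solve_triangular(model._chol, Z.T, lower=True), axis=0)


def mahalanobis_distance(vector: np.ndarray, model: CommonModel) -> float:
    """d = sqrt((x - mu)' Sigma*^-1 (x - mu)) in SD units.

    ``vector`` is on the original feature scale of the model's kept
    features (it is standardised internally with the model's location
    and scale, so the common mean is the origin).
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (len(model.feature_names),):
        raise ConfigError(
            f"vector has {v.shape} entries; model expects "
            f"{len(model.feature_names)}")
    z = (v - model.location) / model.scale
    return float(_distances(model, z[None, :])[0])


def observed_distances(features: CentreFeatureMatrix,
                       model: CommonModel) -> np.ndarray:
    return _distances(model, model.standardise(features.values))


# --------------------------------------------------------------------------
# resampling and flags


def resample_centre_distances(features: CentreFeatureMatrix,
                              model: CommonModel,
                              config: MonitoringConfig | None = None,
                              seed: int | None = None
                              ) -> list[DistanceDistribution]:
    """Bootstrap each included centre's own participants (with
    replacement, sample size = centre size), recompute its summary
    vector, and measure its distance against the fixed common model.

    Reproducible: the same seed gives identical distributions.
    """
    config = config or MonitoringConfig()
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    B = config.n_resamples
    obs = observed_distances(features, model)
    out = []
    for i, centre in enumerate(features.centre_ids):
        V = features.participant_values[centre][:, model.feature_index]
        n = V.shape[0]
        idx = rng.integers(0, n, size=(B, n))
        boot_means = V[idx].mean(axis=1)
        Z = (boot_means - model.location) / model.scale
        out.append(DistanceDistribution(
            centre_id=centre, observed=float(obs[i]),
            distances=_distances(model, Z), n_resamples=B, seed=seed))
    return out


def equivalent_radius(threshold: float, n_features: int) -> float:
    """The p-dimensional distance enclosing the same probability mass as
    the two-sided +/-threshold-SD interval in one dimension."""
    mass = 2.0 * stats.norm.cdf(threshold) - 1.0
    return float(np.sqrt(stats.chi2.ppf(mass, n_features)))


def flag_centres(distributions: list[DistanceDistribution],
                 n_features: int,
                 config: MonitoringConfig | None = None) -> list[CentreFlag]:
    """Two-tier rule against the 2-SD-equivalent radius: *suspected*
    when the median resampled distance is outside, *confirmed* when the
    5% quantile is too (outside even after sampling error)."""
    config = config or MonitoringConfig()
    radius = equivalent_radius(config.distance_threshold, n_features)
    flags = []
    for d in distributions:
        med, q05 = d.median, d.q05
        tier = ("confirmed" if q05 > radius
                else "suspected" if med > radius else "none")
        flags.append(CentreFlag(d.centre_id, tier, d.observed, med, q05,
                                config.distance_threshold, radius))
    return flags


@dataclass
class DetectionResult:
    features: CentreFeatureMatrix
    model: CommonModel
    distributions: list[DistanceDistribution]
    flags: list[CentreFlag]

    def table(self) -> pd.DataFrame:
        rows = []
        for d, f in zip(self.distributions, self.flags):
            rows.append({
                "centre_id": d.centre_id,
                "n_participants": self.features.n_participants[d.centre_id],
                "observed": d.observed,
                **{f"q{int(q * 100):02d}": d.quantile(q) for q in QUANTS},
                "tier": f.tier,
            })
        return pd.DataFrame(rows)

    def exclusions(self) -> pd.DataFrame:
        rows = ([{"what": "centre", "name": c, "reason": r}
                 for c, r in self.features.excluded_centres]
                + [{"what": "feature", "name": n, "reason": r}
                   for n, r in self.features.excluded_features]
                + [{"what": "feature", "name": n, "reason": r}
                   for n, r in self.model.dropped_features])
        return pd.DataFrame(rows, columns=["what", "name", "reason"])


def detect(dataset: TrialDataset, config: MonitoringConfig | None = None,
           seed: int | None = None) -> DetectionResult:
    """Full pipeline: features -> common model -> resampled distances ->
    flags.  Deterministic under the seed."""
    config = config or MonitoringConfig()
    features = build_centre_features(dataset, config)
    model = fit_common_model(features, config)
    distributions = resample_centre_distances(features, model, config, seed)
    flags = flag_centres(distributions, len(model.feature_names), config)
    return DetectionResult(features, model, distributions, flags)


def plot_distances(result: DetectionResult, path) -> None:
    """Box-style summary of each centre's resampled distance distribution
    with the equivalent-radius limit; blinding is the caller's duty."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for i, d in enumerate(result.distributions):
        ax.vlines(i, d.quantile(0.05), d.quantile(0.95), color="0.6")
        ax.scatter([i], [d.observed], color="C0", zorder=3, s=18)
    ax.axhline(result.flags[0].radius if result.flags else 2.0,
               color="C3", ls="--", lw=1)
    ax.set_xticks(range(len(result.distributions)))
    ax.set_xticklabels([d.centre_id for d in result.distributions],
                       rotation=90, fontsize=7)
    ax.set_ylabel("Mahalanobis distance (SD units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
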
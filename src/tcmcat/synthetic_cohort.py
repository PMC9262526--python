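"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the downstream analysis assumes: ~300
patients at baseline with a handful of dropouts before the ~2-week follow-up,
six correlated latent syndrome-element severities, clinician gold-standard
element diagnoses with a small labelling error, eight quality-of-life (QoL)
domains (plus a total score) that respond to severity improvement, and a
5-level global-change anchor (-2 obviously worse ... +2 obviously better).

Default effect sizes follow the reported score trajectories of the source
application: liver and qi-stagnation severities improve most, stomach and
spleen-dampness least. Default anchor cuts are placed on the latent global
change scale so the expected anchor mix resembles the reported follow-up
distribution (3 worse / 93 unchanged / 156 somewhat better / 39 obviously
better out of 291).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import DOMAINS, ELEMENTS, N_DOMAINS, N_ELEMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "anchor_target_calibration",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "total_score",
    "default_qol_loading",
]

# Expected anchor proportions used for default cut placement, expressed as
# counts out of 291: (obviously worse, somewhat worse, no change, somewhat
# better, obviously better). The reported "3 worse" are treated as somewhat
# worse; obviously-worse is given a vanishing share so the cut stays finite.
_DEFAULT_ANCHOR_COUNTS = (0.5, 2.5, 93.0, 156.0, 39.0)


def default_qol_loading() -> np.ndarray:
    """6x8 loading of element improvement on QoL domain change (points per
    logit of severity improvement).

    A broad baseline loading of 1 links every element to every domain;
    emphasized cells encode the qualitative clinical picture: qi deficiency
    drives daily activity, liver and qi stagnation drive anxiety, stomach
    drives diet and discomfort, heat drives coping/health perceptions/stress,
    and spleen-dampness drives sleep with a broad impact on everything else.
    """
    L = np.ones((N_ELEMENTS, N_DOMAINS))
    e = {name: i for i, name in enumerate(ELEMENTS)}
    d = {name: i for i, name in enumerate(DOMAINS)}
    L[e["liver"], d["anxiety"]] = 6.0
    L[e["stomach"], d["diet"]] = 4.0
    L[e["stomach"], d["discomfort"]] = 6.0
    L[e["heat"], d["coping"]] = 6.0
    L[e["heat"], d["health_perceptions"]] = 3.0
    L[e["heat"], d["stress"]] = 2.0
    L[e["heat"], d["anxiety"]] = 2.0
    L[e["spleen_dampness"], :] = 2.0
    L[e["spleen_dampness"], d["sleep"]] = 6.0
    L[e["qi_deficiency"], d["activity"]] = 6.0
    L[e["qi_stagnation"], d["anxiety"]] = 6.0
    return L


def total_score(domain_scores: np.ndarray) -> np.ndarray:
    """Instrument total score: the mean of the eight domain scores.

    The real instrument's aggregation rule is not public; the unweighted mean
    is used throughout and is isolated here so it can be swapped in one place.
    """
    return np.asarray(domain_scores, dtype=float).mean(axis=-1)


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of the generator. All vector fields follow the canonical
    element/domain orderings of :mod:`tcmcat._util`."""

    n_baseline: int = 300
    n_dropout: int = 9
    elements: tuple[str, ...] = ELEMENTS
    severity_mean: tuple[float, ...] = (0.0,) * N_ELEMENTS
    severity_sd: tuple[float, ...] = (1.0,) * N_ELEMENTS
    severity_equicorrelation: float = 0.3
    prevalence_cutoff: tuple[float, ...] = (0.0,) * N_ELEMENTS
    clinician_error_rate: float = 0.05
    # mean latent improvement per element over the follow-up interval;
    # defaults mirror the reported per-element score drops (T-scale / 10)
    treatment_effect: tuple[float, ...] = (0.424, 0.041, 0.095, 0.042, 0.054, 0.186)
    followup_noise_sd: float = 0.3
    qol_loading: tuple = field(
        default_factory=lambda: tuple(map(tuple, default_qol_loading()))
    )
    qol_noise_sd: float = 5.0
    qol_base_mean: float = 60.0
    qol_base_sd: float = 15.0
    baseline_severity_slope: float = 2.0
    anchor_cuts: tuple[float, float, float, float] | None = None
    anchor_misreport_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_dropout < 0 or self.n_dropout >= self.n_baseline:
            raise ValueError("need 0 <= n_dropout < n_baseline")
        if len(self.elements) != N_ELEMENTS:
            raise ValueError("exactly six elements required")
        for name in ("severity_mean", "severity_sd", "prevalence_cutoff", "treatment_effect"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_ELEMENTS,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 6-vector")
        if np.any(np.asarray(self.severity_sd) <= 0):
            raise ValueError("severity_sd must be positive")
        if not 0.0 <= self.clinician_error_rate <= 1.0:
            raise ValueError("clinician_error_rate must be in [0, 1]")
        L = np.asarray(self.qol_loading, dtype=float)
        if L.shape != (N_ELEMENTS, N_DOMAINS) or not np.all(np.isfinite(L)):
            raise ValueError("qol_loading must be a finite 6x8 matrix")
        if self.qol_noise_sd <= 0 or self.qol_base_sd <= 0 or self.followup_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not -1.0 / (N_ELEMENTS - 1) < self.severity_equicorrelation < 1.0:
            raise ValueError("equicorrelation outside the positive-definite range")
        if self.anchor_cuts is not None:
            cuts = np.asarray(self.anchor_cuts, dtype=float)
            if cuts.shape != (4,) or not np.all(np.isfinite(cuts)):
                raise ValueError("anchor_cuts must be four finite values")
            if not np.all(np.diff(cuts) > 0):
                raise ValueError("anchor_cuts must be strictly increasing")
        if not 0.0 <= self.anchor_misreport_rate <= 1.0:
            raise ValueError("anchor_misreport_rate must be in [0, 1]")

    @property
    def n_followup(self) -> int:
        return self.n_baseline - self.n_dropout

    @property
    def loading_matrix(self) -> np.ndarray:
        return np.asarray(self.qol_loading, dtype=float)

    @property
    def severity_covariance(self) -> np.ndarray:
        sd = np.asarray(self.severity_sd, dtype=float)
        rho = self.severity_equicorrelation
        R = np.full((N_ELEMENTS, N_ELEMENTS), rho)
        np.fill_diagonal(R, 1.0)
        return R * np.outer(sd, sd)

    def global_change_moments(self) -> tuple[float, float]:
        """Exact mean and SD of the latent global change g = w . delta_theta,
        where w averages the loading matrix over domains and delta_theta is
        normal with mean ``treatment_effect`` and SD ``followup_noise_sd``."""
        w = self.loading_matrix.mean(axis=1)
        mean_g = float(w @ np.asarray(self.treatment_effect, dtype=float))
        sd_g = float(self.followup_noise_sd * np.linalg.norm(w))
        return mean_g, sd_g

    def resolved_anchor_cuts(self) -> np.ndarray:
        """Anchor cuts in use: the explicit ones, or default cuts placed at
        normal quantiles of the latent global change matching the reference
        anchor mix. Degenerate change distributions get symmetric cuts around
        zero so "no change" maps to the middle level."""
        if self.anchor_cuts is not None:
            return np.asarray(self.anchor_cuts, dtype=float)
        mean_g, sd_g = self.global_change_moments()
        if sd_g <= 1e-9:
            return mean_g + np.array([-1.5, -0.5, 0.5, 1.5])
        counts = np.asarray(_DEFAULT_ANCHOR_COUNTS)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        return mean_g + sd_g * norm.ppf(cum)


@dataclass
class PatientRecord:
    """One patient: latent severities and observables at both timepoints.

    QoL vectors have nine entries (eight domains then the total). Dropped
    patients carry NaN follow-up values and no anchor.
    """

    patient_id: int
    theta_baseline: np.ndarray
    theta_followup: np.ndarray
    clinician_dx_baseline: np.ndarray
    qol_baseline: np.ndarray
    qol_followup: np.ndarray
    anchor: int | None
    dropped: bool

    def __post_init__(self):
        self.theta_baseline = np.asarray(self.theta_baseline, dtype=float)
        self.theta_followup = np.asarray(self.theta_followup, dtype=float)
        self.clinician_dx_baseline = np.asarray(self.clinician_dx_baseline, dtype=int)
        self.qol_baseline = np.asarray(self.qol_baseline, dtype=float)
        self.qol_followup = np.asarray(self.qol_followup, dtype=float)
        if self.qol_baseline.shape != (N_DOMAINS + 1,):
            raise ValueError("qol_baseline must have 9 entries (8 domains + total)")
        if np.nanmin(self.qol_baseline) < 0 or np.nanmax(self.qol_baseline) > 100:
            raise ValueError("QoL scores must lie in [0, 100]")
        qf = self.qol_followup[np.isfinite(self.qol_followup)]
        if qf.size and (qf.min() < 0 or qf.max() > 100):
            raise ValueError("QoL scores must lie in [0, 100]")
        if self.dropped:
            if self.anchor is not None:
                raise ValueError("anchor is undefined for dropped patients")
        else:
            if self.anchor is None or not -2 <= int(self.anchor) <= 2:
                raise ValueError("anchor must be an integer in [-2, 2]")

    def __eq__(self, other):
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.dropped == other.dropped
            and self.anchor == other.anchor
            and np.array_equal(self.theta_baseline, other.theta_baseline)
            and np.array_equal(self.theta_followup, other.theta_followup, equal_nan=True)
            and np.array_equal(self.clinician_dx_baseline, other.clinician_dx_baseline)
            and np.array_equal(self.qol_baseline, other.qol_baseline)
            and np.array_equal(self.qol_followup, other.qol_followup, equal_nan=True)
        )


def _clamp_log(x: np.ndarray, what: str) -> np.ndarray:
    clipped = np.clip(x, 0.0, 100.0)
    n = int(np.sum(clipped != x))
    if n:
        logger.warning("clamped %d %s values to [0, 100]", n, what)
    return clipped


def generate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[PatientRecord]:
    """Draw a cohort from the stated world.

    Model:
      theta_b  ~ MVN(severity_mean, equicorrelated covariance)
      theta_f  = theta_b - treatment_effect + N(0, followup_noise_sd^2)
      dx       = 1{theta_b > prevalence_cutoff} XOR Bernoulli(error_rate)
      dQoL     = (theta_b - theta_f) @ loading + N(0, qol_noise_sd^2), per domain
      anchor   = level of the noiseless latent global change within anchor_cuts
    QoL values are clamped to [0, 100] after noise addition (logged).
    Dropouts are chosen uniformly at random.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_baseline
    mu = np.asarray(config.severity_mean, dtype=float)
    theta_b = rng.multivariate_normal(mu, config.severity_covariance, size=n)
    eta = rng.normal(0.0, config.followup_noise_sd, size=(n, N_ELEMENTS))
    theta_f = theta_b - np.asarray(config.treatment_effect) + eta

    truth = theta_b > np.asarray(config.prevalence_cutoff)
    flips = rng.random((n, N_ELEMENTS)) < config.clinician_error_rate
    dx = (truth ^ flips).astype(int)

    qol_b = (
        config.qol_base_mean
        - config.baseline_severity_slope * theta_b.mean(axis=1, keepdims=True)
        + rng.normal(0.0, config.qol_base_sd, size=(n, N_DOMAINS))
    )
    qol_b = _clamp_log(qol_b, "baseline QoL")

    L = config.loading_matrix
    latent_change = (theta_b - theta_f) @ L  # (n, 8)
    qol_f = qol_b + latent_change + rng.normal(0.0, config.qol_noise_sd, size=(n, N_DOMAINS))
    qol_f = _clamp_log(qol_f, "follow-up QoL")

    g = latent_change.mean(axis=1)
    cuts = config.resolved_anchor_cuts()
    anchor = np.searchsorted(cuts, g, side="right") - 2
    if config.anchor_misreport_rate > 0:
        mis = rng.random(n) < config.anchor_misreport_rate
        shift = rng.choice([-1, 1], size=n)
        anchor = np.where(mis, np.clip(anchor + shift, -2, 2), anchor)

    dropped_idx = set(rng.choice(n, size=config.n_dropout, replace=False).tolist())

    records = []
    for i in range(n):
        dropped = i in dropped_idx
        qb = np.append(qol_b[i], total_score(qol_b[i]))
        qf = np.append(qol_f[i], total_score(qol_f[i]))
        records.append(
            PatientRecord(
                patient_id=i + 1,
                theta_baseline=theta_b[i],
                theta_followup=np.full(N_ELEMENTS, np.nan) if dropped else theta_f[i],
                clinician_dx_baseline=dx[i],
                qol_baseline=qb,
                qol_followup=np.full(N_DOMAINS + 1, np.nan) if dropped else qf,
                anchor=None if dropped else int(anchor[i]),
                dropped=dropped,
            )
        )
    return records


def anchor_target_calibration(
    config: CohortConfig,
    target_counts: tuple[int, int, int, int],
    n_replicates: int = 50,
    rng: np.random.Generator | None = None,
) -> CohortConfig:
    """Adjust ``anchor_cuts`` so expected anchor counts approximate targets.

    ``target_counts`` is (obviously better, somewhat better, worse, unchanged)
    and must sum to the follow-up count. The latent global change is sampled
    over ``n_replicates`` cohorts; cuts are placed at normal quantiles of its
    estimated mean/SD (the latent change is exactly normal under the
    generator), which is far more stable than raw empirical quantiles for
    small tail targets.
    """
    targets = np.asarray(target_counts, dtype=float)
    if targets.shape != (4,) or np.any(targets < 0):
        raise ValueError("target_counts must be four non-negative integers")
    if int(targets.sum()) != config.n_followup:
        raise ValueError(
            f"targets must sum to the follow-up count {config.n_followup}, "
            f"got {int(targets.sum())}"
        )
    rng = rng or np.random.default_rng(config.seed)
    t = np.asarray(config.treatment_effect, dtype=float)
    w = config.loading_matrix.mean(axis=1)
    m = n_replicates * config.n_baseline
    delta = t + rng.normal(0.0, config.followup_noise_sd, size=(m, N_ELEMENTS))
    g = delta @ w
    mean_g, sd_g = float(g.mean()), float(g.std(ddof=1))

    obv_better, smw_better, worse, unchanged = targets
    total = targets.sum()
    cum = np.array([worse, worse + unchanged, worse + unchanged + smw_better]) / total
    lo, hi = g.min() - 3.0, g.max() + 3.0
    cuts = [lo - 1.0]  # obviously-worse bin kept empty: all worse map to -1
    for q in cum:
        if q <= 0.0:
            c = lo
        elif q >= 1.0:
            c = hi
        elif sd_g <= 1e-9:
            c = mean_g
        else:
            c = mean_g + sd_g * norm.ppf(q)
        cuts.append(c)
    cuts = np.asarray(cuts)
    for k in range(1, 4):
        cuts[k] = max(cuts[k], cuts[k - 1] + 1e-6)
    return dataclasses.replace(config, anchor_cuts=tuple(cuts))


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = (
    ["patient_id", "dropped", "anchor"]
    + [f"theta_b_{e}" for e in ELEMENTS]
    + [f"theta_f_{e}" for e in ELEMENTS]
    + [f"dx_{e}" for e in ELEMENTS]
    + [f"qol_b_{d}" for d in list(DOMAINS) + ["total"]]
    + [f"qol_f_{d}" for d in list(DOMAINS) + ["total"]]
)


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "dropped": int(r.dropped),
            "anchor": r.anchor if r.anchor is not None else np.nan,
        }
        for j, e in enumerate(ELEMENTS):
            row[f"theta_b_{e}"] = r.theta_baseline[j]
            row[f"theta_f_{e}"] = r.theta_followup[j]
            row[f"dx_{e}"] = r.clinician_dx_baseline[j]
        for j, d in enumerate(list(DOMAINS) + ["total"]):
            row[f"qol_b_{d}"] = r.qol_baseline[j]
            row[f"qol_f_{d}"] = r.qol_followup[j]
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed cohort header; missing columns: {missing}")
    if df.empty:
        raise ValueError("no records")
    records = []
    for _, row in df.iterrows():
        dropped = bool(int(row["dropped"]))
        anchor = None
        if not dropped:
            if pd.isna(row["anchor"]):
                raise ValueError("anchor missing for a non-dropped patient")
            a = float(row["anchor"])
            if a != int(a) or not -2 <= a <= 2:
                raise ValueError(f"anchor out of range: {row['anchor']}")
            anchor = int(a)
        records.append(
            PatientRecord(
                patient_id=int(row["patient_id"]),
                theta_baseline=np.array([row[f"theta_b_{e}"] for e in ELEMENTS]),
                theta_followup=np.array([row[f"theta_f_{e}"] for e in ELEMENTS]),
                clinician_dx_baseline=np.array(
                    [int(row[f"dx_{e}"]) for e in ELEMENTS]
                ),
                qol_baseline=np.array(
                    [row[f"qol_b_{d}"] for d in list(DOMAINS) + ["total"]]
                ),
                qol_followup=np.array(
                    [row[f"qol_f_{d}"] for d in list(DOMAINS) + ["total"]]
                ),
                anchor=anchor,
                dropped=dropped,
            )
        )
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    # %.17g keeps the binary float round trip exact
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> list[PatientRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError("no records") from exc
    return frame_to_cohort(df)
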
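"""Synthetic cohorts with the structure the analysis assumes.

Each subject carries a latent smooth multivariate trajectory built from K
shared principal components: marker j follows

    X_ij(t) = mu_j(t) + sum_k rho_ik * c_jk * phi_k(t),   t in [0, 12] months,

with subject scores rho_ik ~ N(0, lambda_k), per-marker loadings c_jk, and
orthonormal component functions phi_k (Fourier cosine basis on [0, 12]).
Observations are the latent curve at irregular visit times ({0} plus a Poisson
process on (0, 12]) plus i.i.d. Gaussian measurement error. Progression times
come from a Weibull proportional-hazards model whose linear predictor combines
baseline covariates (gamma) and the latent scores (alpha); overall survival
adds an exponential post-progression gap, and administrative censoring is
uniform. Full ground truth (scores, linear predictors, conditional survival)
is returned for parameter-recovery and dynamic-prediction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BASELINE_COVARIATES, Cohort, SubjectRecord

T_MAX = 12.0


class GenerationError(RuntimeError):
    """The configuration cannot produce a usable cohort."""


def eigenfunction_basis(t, n_components: int) -> np.ndarray:
    """Orthonormal component basis on [0, T_MAX]: rows=times, cols=components.

    phi_1 = 1/sqrt(T) is the trajectory *level*, visible already in the
    preoperative (t=0) value; phi_k = sqrt(2/T) * sin(2(k-1) * pi * t / T) for
    k >= 2 are postoperative *shape* components that vanish at t=0, so their
    scores cannot be read off the baseline measurement. The set is orthonormal
    under the L2 inner product on [0, T].
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((t.size, n_components))
    out[:, 0] = 1.0 / np.sqrt(T_MAX)
    for k in range(1, n_components):
        out[:, k] = np.sqrt(2.0 / T_MAX) * np.sin(2 * k * np.pi * t / T_MAX)
    return out


def _default_loadings(n_markers: int, n_components: int) -> np.ndarray:
    # fixed, structured loading pattern: every marker loads on every component
    # with varying magnitude and sign so components are genuinely shared
    rng = np.random.default_rng(20231104)
    mags = rng.uniform(0.5, 1.2, size=(n_markers, n_components))
    signs = rng.choice([-1.0, 1.0], size=(n_markers, n_components))
    return mags * signs


def _default_mean_params(n_markers: int) -> np.ndarray:
    # mu_j(t) = b0 + b1 * exp(-t/2): a post-surgery normalization transient
    rng = np.random.default_rng(772200)
    return rng.uniform(-1.0, 1.0, size=(n_markers, 2))


#: Baseline covariate distributions loosely matching a resected CRLM cohort:
#: (distribution, params). Hazard log-coefficients gamma are zero except for a
#: handful of established prognostic factors.
DEFAULT_BASELINE_SPEC: dict[str, tuple] = {
    "age": ("normal", (59.0, 10.0)),
    "male_sex": ("bernoulli", (0.627,)),
    "comorbidity": ("bernoulli", (0.419,)),
    "asa_1_2": ("bernoulli", (0.927,)),
    "preop_chemotherapy": ("bernoulli", (0.636,)),
    "primary_colon": ("bernoulli", (0.685,)),
    "right_hemicolon": ("bernoulli", (0.276,)),
    "bilobar_distribution": ("bernoulli", (0.44,)),
    "n_liver_metastases": ("poisson1p", (1.5,)),
    "diameter_liver_metastases_cm": ("lognormal", (0.83, 0.55)),
    "extrahepatic_metastases": ("bernoulli", (0.113,)),
    "major_liver_resection": ("bernoulli", (0.342,)),
    "r0_resection": ("bernoulli", (0.781,)),
    "poor_differentiation": ("bernoulli", (0.246,)),
    "t3_t4_stage": ("bernoulli", (0.908,)),
    "n1_n2_stage": ("bernoulli", (0.653,)),
    "kras_mutation": ("bernoulli", (0.309,)),
    "adjuvant_chemotherapy": ("bernoulli", (0.705,)),
}

DEFAULT_GAMMA: dict[str, float] = {
    "bilobar_distribution": 0.25,
    "n_liver_metastases": 0.08,
    "diameter_liver_metastases_cm": 0.06,
    "extrahepatic_metastases": 0.40,
    "r0_resection": -0.30,
    "n1_n2_stage": 0.20,
}


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions.

    ``visit_rate`` is the expected number of postoperative visits in the first
    12 months (Poisson, resampled to guarantee at least 2). ``alpha`` couples
    the hazard to the latent component scores; ``gamma`` to baseline
    covariates. Censoring is administrative, uniform on
    [censor_low, censor_high] months.
    """

    n_subjects: int = 300
    n_markers: int = 9
    eigenvalues: tuple = (6.0, 3.0, 1.5)
    loadings: np.ndarray | None = None
    mean_params: np.ndarray | None = None
    noise_sd: float | tuple = 0.5
    visit_rate: float = 5.0
    baseline_spec: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_SPEC))
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    alpha: tuple = (0.25, 0.35, 0.30)
    weibull_shape: float = 1.2
    weibull_scale: float = 28.0
    os_gap_mean: float = 18.0
    censor_low: float = 6.0
    censor_high: float = 60.0
    missing_rate: float = 0.0
    skew_transform: bool = False
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def marker_names(self) -> tuple:
        return tuple(f"marker_{j + 1:02d}" for j in range(self.n_markers))

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            c = np.asarray(self.loadings, dtype=float)
            if c.shape != (self.n_markers, self.n_components):
                raise GenerationError(
                    f"loadings shape {c.shape} != "
                    f"({self.n_markers}, {self.n_components})"
                )
            return c
        return _default_loadings(self.n_markers, self.n_components)

    def resolved_mean_params(self) -> np.ndarray:
        if self.mean_params is not None:
            return np.asarray(self.mean_params, dtype=float)
        return _default_mean_params(self.n_markers)

    def resolved_noise_sd(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.noise_sd, float), (self.n_markers,))
        return np.array(s)

    def validate(self):
        lam = np.asarray(self.eigenvalues, float)
        if lam.ndim != 1 or lam.size < 1:
            raise GenerationError("eigenvalues must be a non-empty sequence")
        if not (np.diff(lam) < 0).all():
            raise GenerationError("eigenvalues must be strictly decreasing")
        if (lam <= 0).any():
            raise GenerationError("eigenvalues must be positive")
        if (self.resolved_noise_sd() <= 0).any():
            raise GenerationError("noise_sd must be positive")
        if self.visit_rate <= 0:
            raise GenerationError("visit_rate must be positive")
        if len(self.alpha) != self.n_components:
            raise GenerationError("alpha length must equal number of components")
        if not 0 <= self.missing_rate < 1:
            raise GenerationError("missing_rate must be in [0, 1)")
        if self.censor_low <= 0 or self.censor_high <= self.censor_low:
            raise GenerationError("need 0 < censor_low < censor_high")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort."""

    scores: np.ndarray            # (n, K) true component scores rho_i
    linear_predictor: np.ndarray  # (n,) gamma'x + alpha'rho (progression hazard)
    weibull_shape: float
    weibull_scale: float
    eigenvalues: np.ndarray
    loadings: np.ndarray
    noise_sd: np.ndarray
    mean_params: np.ndarray
    subject_ids: list
    resample_count: int = 0

    def mean_function(self, marker_index: int, t) -> np.ndarray:
        b0, b1 = self.mean_params[marker_index]
        return b0 + b1 * np.exp(-np.asarray(t, float) / 2.0)

    def latent_curve(self, subject_index: int, marker_index: int, t) -> np.ndarray:
        phi = eigenfunction_basis(t, len(self.eigenvalues))
        contrib = phi @ (self.scores[subject_index] * self.loadings[marker_index])
        return self.mean_function(marker_index, t) + contrib

    def cumulative_hazard(self, subject_index: int, t) -> np.ndarray:
        t = np.asarray(t, float)
        lam0 = (t / self.weibull_scale) ** self.weibull_shape
        return lam0 * np.exp(self.linear_predictor[subject_index])

    def survival(self, subject_index: int, t) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(subject_index, t))


def true_conditional_survival(
    truth: SimulationTruth, subject_index: int, s: float, t
) -> np.ndarray:
    """Exact S_i(t)/S_i(s) of the progression process; oracle for landmarking."""
    t = np.asarray(t, dtype=float)
    if np.any(t < s) or s < 0:
        raise ValueError("require 0 <= s <= t")
    out = np.exp(
        -(truth.cumulative_hazard(subject_index, t)
          - truth.cumulative_hazard(subject_index, s))
    )
    return out if out.shape else float(out)


def simulate_visit_schedule(config: SimulationConfig, rng: np.random.Generator):
    """Visit times for one subject: {0} plus >=2 Poisson-process times in (0, 12].

    Returns (times, n_resamples); schedules with fewer than 2 postoperative
    visits are redrawn so every generated subject passes eligibility.
    """
    resamples = 0
    while True:
        n_visits = rng.poisson(config.visit_rate)
        if n_visits >= 2:
            break
        resamples += 1
        if resamples > 10_000:
            raise GenerationError(
                "visit_rate too low to produce 2 postoperative visits"
            )
    post = np.sort(rng.uniform(0.0, T_MAX, size=n_visits))
    post = np.unique(np.maximum(post, 1e-6))
    return np.concatenate([[0.0], post]), resamples


def _draw_baseline(spec: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, (dist, params) in spec.items():
        if dist == "normal":
            cols[name] = rng.normal(params[0], params[1], n)
        elif dist == "bernoulli":
            cols[name] = (rng.random(n) < params[0]).astype(float)
        elif dist == "poisson1p":
            cols[name] = 1.0 + rng.poisson(params[0], n)
        elif dist == "lognormal":
            cols[name] = rng.lognormal(params[0], params[1], n)
        else:
            raise GenerationError(f"unknown baseline distribution {dist!r}")
    return pd.DataFrame(cols)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Generate a cohort plus its ground truth. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, J, K = config.n_subjects, config.n_markers, config.n_components
    lam = np.asarray(config.eigenvalues, float)
    loadings = config.resolved_loadings()
    mean_params = config.resolved_mean_params()
    noise_sd = config.resolved_noise_sd()
    names = config.marker_names()

    baseline = _draw_baseline(config.baseline_spec, n, rng)
    scores = rng.normal(size=(n, K)) * np.sqrt(lam)

    gamma = np.array([config.gamma.get(c, 0.0) for c in baseline.columns])
    # center covariates in the hazard so gamma acts on deviations, keeping the
    # marginal event fraction governed by the Weibull baseline
    x = baseline.to_numpy(float)
    eta = (x - x.mean(axis=0)) @ gamma + scores @ np.asarray(config.alpha)

    # inverse-transform sampling from the Weibull proportional-hazards model
    u = rng.exponential(size=n)  # = -log(U)
    t_prog = config.weibull_scale * (u * np.exp(-eta)) ** (1.0 / config.weibull_shape)
    gap = rng.exponential(config.os_gap_mean, size=n)
    t_death = t_prog + gap
    censor = rng.uniform(config.censor_low, config.censor_high, size=n)

    pfs_time = np.minimum(t_prog, censor)
    pfs_event = t_prog <= censor
    os_time = np.minimum(t_death, censor)
    os_event = t_death <= censor
    if not pfs_event.any():
        raise GenerationError("configuration produced an all-censored cohort")

    subjects = []
    total_resamples = 0
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    for i in range(n):
        times, res = simulate_visit_schedule(config, rng)
        total_resamples += res
        phi = eigenfunction_basis(times, K)  # (T, K)
        latent = (
            mean_params[:, 0][:, None]
            + mean_params[:, 1][:, None] * np.exp(-times / 2.0)[None, :]
            + (loadings * scores[i]) @ phi.T
        )  # (J, T)
        obs = latent + rng.normal(size=latent.shape) * noise_sd[:, None]
        if config.skew_transform:
            obs = np.exp(obs)
        rows = []
        for j in range(J):
            for ti, t in enumerate(times):
                if config.missing_rate and rng.random() < config.missing_rate:
                    continue
                rows.append((names[j], float(t), float(obs[j, ti])))
        meas = pd.DataFrame(rows, columns=["marker", "time_months", "value"])
        subjects.append(
            SubjectRecord(
                subject_id=subject_ids[i],
                baseline={c: float(baseline.iloc[i][c]) for c in baseline.columns},
                measurements=meas,
                pfs_time_months=float(max(pfs_time[i], 1e-3)),
                pfs_event=bool(pfs_event[i]),
                os_time_months=float(max(os_time[i], 1e-3)),
                os_event=bool(os_event[i]),
            )
        )

    cohort = Cohort(
        subjects,
        marker_names=names,
        provenance={"source": "synthetic", "seed": config.seed},
    )
    truth = SimulationTruth(
        scores=scores,
        linear_predictor=eta,
        weibull_shape=config.weibull_shape,
        weibull_scale=config.weibull_scale,
        eigenvalues=lam,
        loadings=loadings,
        noise_sd=noise_sd,
        mean_params=mean_params,
        subject_ids=subject_ids,
        resample_count=total_resamples,
    )
    return cohort, truth
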
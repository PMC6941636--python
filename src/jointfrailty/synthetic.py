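"""Synthetic cohorts with correlated log-normal frailties and known truth.

The generator emulates a breast-cancer-like registry cohort followed from
surgery: two recurrent-event processes (local recurrence, metastasis) whose
subject-level log-frailties ``(u_i, v_i)`` are bivariate normal with
variances ``theta``, ``eta`` and correlation ``rho``; proportional-hazards
effects of fixed categorical covariates; independent right censoring by an
administrative horizon and exponential dropout; and an optional terminal
event (death) whose log-hazard loads on both frailties through ``alpha_1 u +
alpha_2 v``.

Conditionally on the frailty pair and covariates, each recurrent process is
an inhomogeneous Poisson process on calendar time with intensity
``h_k(t) exp(beta_k' Z + b_k)``; successive event times are generated by
closed-form inversion of the cumulative hazard, so no root-finding noise
enters the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    LOCAL, METASTASIS, TERMINAL, EVENT_COLUMNS,
    CovariateSchema, EventHistory,
)


class ParameterError(ValueError):
    """Invalid simulation or distribution parameter."""


@dataclass(frozen=True)
class FrailtyCovariance:
    """Law of the log-frailty pair: variances ``theta``, ``eta``, correlation ``rho``.

    ``rho`` is treated as 0 when either variance is 0 (the degenerate
    component carries no dependence).
    """

    theta: float
    eta: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.theta < 0 or self.eta < 0:
            raise ParameterError("frailty variances must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ParameterError("frailty correlation must lie in (-1, 1)")

    @property
    def effective_rho(self) -> float:
        return 0.0 if (self.theta == 0 or self.eta == 0) else self.rho

    def matrix(self) -> np.ndarray:
        r = self.effective_rho
        cov = r * np.sqrt(self.theta * self.eta)
        return np.array([[self.theta, cov], [cov, self.eta]])

    def cholesky(self) -> np.ndarray:
        """Lower-triangular L with L L' = Sigma (valid for semi-definite corners)."""
        s1, s2 = np.sqrt(self.theta), np.sqrt(self.eta)
        r = self.effective_rho
        return np.array([[s1, 0.0], [s2 * r, s2 * np.sqrt(1.0 - r * r)]])


# ---------------------------------------------------------------------------
# parametric baseline hazards with closed-form inverse cumulative hazards


@dataclass(frozen=True)
class WeibullHazard:
    """h(t) = (shape/scale) (t/scale)^(shape-1); Lambda(t) = (t/scale)^shape."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError("Weibull shape and scale must be > 0")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)

    def cumulative_hazard(self, t):
        return (np.asarray(t, dtype=float) / self.scale) ** self.shape

    def inverse_cumulative_hazard(self, H):
        return self.scale * np.asarray(H, dtype=float) ** (1.0 / self.shape)


@dataclass(frozen=True)
class PiecewiseConstantHazard:
    """Piecewise-constant rates on intervals split at ``cutpoints``.

    ``rates`` has one more entry than ``cutpoints``; the final rate extends
    to infinity.  The cumulative hazard is piecewise linear and inverted
    exactly.
    """

    rates: tuple[float, ...]
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.cutpoints) + 1:
            raise ParameterError("need len(rates) == len(cutpoints) + 1")
        if any(r < 0 for r in self.rates) or self.rates[-1] <= 0:
            raise ParameterError("rates must be >= 0 with final rate > 0")
        cp = np.asarray(self.cutpoints, dtype=float)
        if cp.size and (np.any(np.diff(cp) <= 0) or cp[0] <= 0):
            raise ParameterError("cutpoints must be strictly increasing and > 0")

    def _grid(self):
        edges = np.concatenate([[0.0], np.asarray(self.cutpoints, dtype=float)])
        rates = np.asarray(self.rates, dtype=float)
        cumH = np.zeros(edges.size)
        cumH[1:] = np.cumsum(rates[:-1] * np.diff(edges))
        return edges, rates, cumH

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        edges, rates, _ = self._grid()
        idx = np.searchsorted(edges, t, side="right") - 1
        return rates[np.clip(idx, 0, len(rates) - 1)]

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        edges, rates, cumH = self._grid()
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(rates) - 1)
        return cumH[idx] + rates[idx] * (t - edges[idx])

    def inverse_cumulative_hazard(self, H):
        H = np.asarray(H, dtype=float)
        edges, rates, cumH = self._grid()
        idx = np.clip(np.searchsorted(cumH, H, side="right") - 1, 0, len(rates) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = edges[idx] + (H - cumH[idx]) / rates[idx]
        return np.where(np.isfinite(out), out, np.inf)


Baseline = WeibullHazard | PiecewiseConstantHazard


@dataclass(frozen=True)
class CategoricalModel:
    """Sampling probabilities over a categorical covariate's levels."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ParameterError("levels and probs length mismatch")
        if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
            raise ParameterError("probs must be nonnegative and sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generating mechanism for one synthetic cohort.

    ``beta_1`` / ``beta_2`` / ``beta_d`` map covariate name -> {level: log-HR}
    (reference levels implicitly 0); a numeric covariate maps name -> coef.
    Horizon is the administrative censoring time in months; ``dropout_rate``
    an exponential loss-to-follow-up rate per month (0 disables dropout).
    """

    n_subjects: int
    schema: CovariateSchema
    covariate_model: dict[str, CategoricalModel]
    baseline_1: Baseline
    baseline_2: Baseline
    frailty: FrailtyCovariance
    beta_1: dict[str, dict[str, float] | float] = field(default_factory=dict)
    beta_2: dict[str, dict[str, float] | float] = field(default_factory=dict)
    beta_d: dict[str, dict[str, float] | float] = field(default_factory=dict)
    baseline_d: Baseline | None = None
    alpha_1: float = 0.0
    alpha_2: float = 0.0
    include_terminal: bool = False
    horizon: float = 120.0
    dropout_rate: float = 0.0
    max_recurrences_per_type: int = 50
    min_followup: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.horizon <= 0:
            raise ParameterError("horizon must be > 0")
        if self.dropout_rate < 0:
            raise ParameterError("dropout_rate must be >= 0")
        if self.max_recurrences_per_type < 1:
            raise ParameterError("max_recurrences_per_type must be >= 1")
        if self.include_terminal and self.baseline_d is None:
            raise ParameterError("terminal submodel enabled but baseline_d missing")
        for betas, names in ((self.beta_1, self.schema.design_1),
                             (self.beta_2, self.schema.design_2),
                             (self.beta_d, self.schema.design_d)):
            for name in betas:
                if name not in names:
                    raise ParameterError(
                        f"beta for {name!r} has no matching design column")

    def linear_predictor(self, betas: dict, covariates: pd.DataFrame,
                         design_names: tuple[str, ...]) -> np.ndarray:
        """beta' Z for every subject, on the declared dummy encoding."""
        lp = np.zeros(len(covariates))
        for name in design_names:
            spec = betas.get(name)
            if spec is None:
                continue
            cov = self.schema[name]
            if cov.is_categorical:
                for level, b in spec.items():
                    if level not in cov.levels:
                        raise ParameterError(f"beta level {level!r} unknown for {name!r}")
                    if level == cov.reference:
                        raise ParameterError(
                            f"beta given for reference level of {name!r}")
                    lp += b * (covariates[name].to_numpy() == level)
            else:
                lp += float(spec) * covariates[name].to_numpy(dtype=float)
        return lp

    def true_beta_vector(self, event_type: str) -> tuple[np.ndarray, list[str]]:
        """Ground-truth coefficients on the schema's dummy columns."""
        names = self.schema.design_for(event_type)
        betas = {LOCAL: self.beta_1, METASTASIS: self.beta_2,
                 TERMINAL: self.beta_d}[event_type]
        vals, labels = [], []
        for name, level in self.schema.design_columns(tuple(names)):
            if level is None:
                vals.append(float(betas.get(name, 0.0)))
                labels.append(name)
            else:
                vals.append(float(betas.get(name, {}).get(level, 0.0)))
                labels.append(f"{name}[{level}]")
        return np.array(vals), labels


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that an analyst would not observe."""

    config: SimulationConfig
    frailties: pd.DataFrame  # subject_id, u, v
    followup: pd.DataFrame   # subject_id, followup, death (0/1)

    def to_frame(self) -> pd.DataFrame:
        return self.frailties.merge(self.followup, on="subject_id")


def draw_frailties(n: int, cov: FrailtyCovariance, seed: int | np.random.Generator
                   ) -> np.ndarray:
    """``(n, 2)`` i.i.d. draws of (u, v) from N(0, Sigma(theta, eta, rho))."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    return z @ cov.cholesky().T


def _recurrent_times(baseline: Baseline, log_mult: float, followup: float,
                     cap: int, rng: np.random.Generator) -> np.ndarray:
    """Event times of one Poisson process with intensity h(t) e^{log_mult} on (0, followup]."""
    mult = np.exp(log_mult)
    times = []
    H = 0.0  # accumulated baseline cumulative hazard at the previous event
    t_prev = 0.0
    for _ in range(cap):
        H = H + rng.exponential() / mult
        t = float(baseline.inverse_cumulative_hazard(H))
        if not t > t_prev:  # numeric guard; zero-length gap has probability 0
            t = np.nextafter(t_prev, np.inf)
        if t >= followup:
            break
        times.append(t)
        t_prev = t
    return np.asarray(times)


def simulate_subject(config: SimulationConfig, subject_id: str,
                     frailty: tuple[float, float],
                     covariate_row: pd.DataFrame,
                     rng: np.random.Generator) -> list[dict]:
    """Counting-process records for one subject given their frailty pair.

    Follow-up ends at min(terminal event, dropout, horizon); each recurrent
    process contributes its event intervals plus one final censored interval,
    and a single terminal record is emitted when the terminal submodel is on.
    """
    u, v = frailty
    lp1 = float(config.linear_predictor(config.beta_1, covariate_row,
                                        config.schema.design_1)[0])
    lp2 = float(config.linear_predictor(config.beta_2, covariate_row,
                                        config.schema.design_2)[0])

    followup = config.horizon
    death = 0
    if config.dropout_rate > 0:
        followup = min(followup, rng.exponential(1.0 / config.dropout_rate))
    if config.include_terminal:
        lpd = float(config.linear_predictor(config.beta_d, covariate_row,
                                            config.schema.design_d)[0])
        lpd += config.alpha_1 * u + config.alpha_2 * v
        Hd = rng.exponential() / np.exp(lpd)
        td = float(config.baseline_d.inverse_cumulative_hazard(Hd))
        if td < followup:
            followup = td
            death = 1
    followup = max(followup, config.min_followup)

    records: list[dict] = []
    for etype, baseline, lp, b in ((LOCAL, config.baseline_1, lp1, u),
                                   (METASTASIS, config.baseline_2, lp2, v)):
        times = _recurrent_times(baseline, lp + b, followup,
                                 config.max_recurrences_per_type, rng)
        start = 0.0
        for t in times:
            records.append({"subject_id": subject_id, "event_type": etype,
                            "start": start, "stop": float(t), "status": 1})
            start = float(t)
        if followup > start:
            records.append({"subject_id": subject_id, "event_type": etype,
                            "start": start, "stop": float(followup), "status": 0})
    if config.include_terminal:
        records.append({"subject_id": subject_id, "event_type": TERMINAL,
                        "start": 0.0, "stop": float(followup), "status": death})
    return records


def draw_covariates(config: SimulationConfig, rng: np.random.Generator
                    ) -> pd.DataFrame:
    """One covariate row per subject from the configured category probabilities."""
    n = config.n_subjects
    width = len(str(n))
    data = {"subject_id": [f"s{str(i + 1).zfill(width)}" for i in range(n)]}
    for name in config.schema.names:
        model = config.covariate_model.get(name)
        if model is None:
            raise ParameterError(f"no covariate model for {name!r}")
        data[name] = rng.choice(model.levels, size=n, p=model.probs)
    return pd.DataFrame(data)


def simulate_cohort(config: SimulationConfig) -> tuple[EventHistory, GroundTruth]:
    """Simulate ``n_subjects`` independent subjects; return cohort + ground truth.

    One independent random substream per subject (spawned from the master
    seed) makes per-subject draws reproducible under reordering.  The output
    always satisfies the counting-process invariants by construction.
    """
    master = np.random.SeedSequence(config.seed)
    cov_seed, frailty_seed, subject_root = master.spawn(3)
    rng_cov = np.random.default_rng(cov_seed)
    covariates = draw_covariates(config, rng_cov)
    frailties = draw_frailties(config.n_subjects, config.frailty,
                               np.random.default_rng(frailty_seed))

    records: list[dict] = []
    followups: list[dict] = []
    subject_streams = subject_root.spawn(config.n_subjects)
    for i, (subject_id, stream) in enumerate(zip(covariates["subject_id"],
                                                 subject_streams)):
        rng = np.random.default_rng(stream)
        row = covariates.iloc[[i]]
        recs = simulate_subject(config, subject_id, tuple(frailties[i]), row, rng)
        records.extend(recs)
        fu = max(r["stop"] for r in recs)
        death = any(r["event_type"] == TERMINAL and r["status"] == 1 for r in recs)
        followups.append({"subject_id": subject_id, "followup": fu,
                          "death": int(death)})

    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    history = EventHistory(events=events, covariates=covariates,
                           schema=config.schema)
    truth = GroundTruth(
        config=config,
        frailties=pd.DataFrame({"subject_id": covariates["subject_id"],
                                "u": frailties[:, 0], "v": frailties[:, 1]}),
        followup=pd.DataFrame(followups),
    )
    return history, truth
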
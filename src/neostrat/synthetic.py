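"""Registry-shaped synthetic cohorts with planted ground truth.

Emulates the structure of a national neonatal registry: an episodic admission
table (one row per care episode, covariates possibly missing on later
episodes), a daily table (one row per infant-day with six binary nutrition
components, daily weight and a respiratory-support flag), and a ground-truth
record of which nutritional archetype each infant was drawn from.

Nutritional practice is planted as cluster archetypes: each archetype is a
Gaussian over the six proportion-of-days components.  A draw is clipped to
[0, 1], converted to per-component day-counts over the infant's stay, and
realised as a day sequence using component-specific timeline weights
(parenteral components front-loaded, formula and fortifier ramping up), so
that timeline summaries of the generated data are non-trivial.

Outcomes are generated with stated effect sizes: continuous outcomes as
baseline + covariate effects + archetype effect + Gaussian noise, binary
outcomes through logistic models, and then *realised into the raw tables*
(death as a discharge destination, chronic-lung-disease as a respiratory flag
at 36 weeks postmenstrual age, weight trajectories hitting the planted
36-week z-score) so that curation has to re-derive them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .constants import COMPONENTS, REGIONS
from .errors import ConfigurationError
from .lms import LMSReference, lms_weight

EPISODE_COLUMNS = [
    "infant_id", "admission_time", "birth_time", "ga_weeks", "birth_weight_g",
    "sex", "antenatal_steroids", "resuscitation", "apgar1", "apgar5",
    "apgar10", "imd_decile", "smoking", "region", "discharge_destination",
    "severe_nec",
]

DAILY_COLUMNS = ["infant_id", "timestamp"] + COMPONENTS + [
    "weight_g", "respiratory_support",
]

#: Exponential timeline rates w(u) = exp(rate * u) over normalised stay u:
#: negative = front-loaded, positive = ramping up towards discharge.
TIMELINE_RATES = {"MM": 0.0, "HDM": -2.0, "BMF": 1.5, "FM": 3.0, "PN": -5.0, "GE": -4.0}

#: Gestational-age distribution over completed weeks 22..31 (relative sizes
#: of the GA strata in a very-preterm population; rises steeply with GA).
GA_WEEKS = np.arange(22, 32)
GA_WEIGHTS = np.array([55, 1217, 2277, 2607, 3304, 4239, 5599, 6555, 8503, 11323], float)
GA_PROBS = GA_WEIGHTS / GA_WEIGHTS.sum()


@dataclass
class ClusterArchetype:
    """A planted nutritional pattern.

    mean_proportions / covariance parameterise the Gaussian over the six
    proportion-of-days components; admission_shift applies additive offsets
    to admission covariates (keys: ga_weeks, bw_zscore); outcome_effects are
    additive on continuous outcomes and log-odds shifts on binary outcomes
    (keys: w36_zscore, bpd, mortality, severe_nec).
    """

    name: str
    mean_proportions: np.ndarray
    covariance: np.ndarray
    weight: float
    admission_shift: dict = field(default_factory=dict)
    outcome_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean_proportions = np.asarray(self.mean_proportions, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean_proportions.shape != (6,):
            raise ConfigurationError(f"{self.name}: mean_proportions must be a 6-vector")
        if np.any(self.mean_proportions < 0) or np.any(self.mean_proportions > 1):
            raise ConfigurationError(f"{self.name}: mean_proportions must lie in [0,1]")
        if self.covariance.shape != (6, 6):
            raise ConfigurationError(f"{self.name}: covariance must be 6x6")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ConfigurationError(f"{self.name}: covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.covariance)) < -1e-10:
            raise ConfigurationError(f"{self.name}: covariance must be PSD")
        if not 0 <= self.weight <= 1:
            raise ConfigurationError(f"{self.name}: weight must be a probability")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_proportions"] = self.mean_proportions.tolist()
        d["covariance"] = self.covariance.tolist()
        return d


def _cov(sd: float, anticorr_mm_fm: float = 0.0) -> np.ndarray:
    cov = np.eye(6) * sd ** 2
    cov[0, 3] = cov[3, 0] = anticorr_mm_fm * sd * sd
    return cov


def default_archetypes() -> list[ClusterArchetype]:
    """Three well-separated archetypes patterned on common practice.

    A formula/maternal-milk trade-off group, a maternal-milk-dominant group
    with fortifier, and a parenteral-intensive group of sicker, more preterm
    infants with elevated mortality and lung-disease risk.  Means are kept in
    the interior of [0,1]; within-archetype sd is 0.06 with a mild MM-FM
    anticorrelation in the trade-off group.
    """
    return [
        ClusterArchetype(
            name="formula-mix",
            mean_proportions=[0.55, 0.12, 0.14, 0.70, 0.22, 0.16],
            covariance=_cov(0.05, anticorr_mm_fm=-0.4),
            weight=0.5,
            admission_shift={"ga_weeks": 1.0},
            outcome_effects={"w36_zscore": 0.15, "bpd": 0.3},
        ),
        ClusterArchetype(
            name="maternal-milk",
            mean_proportions=[0.90, 0.12, 0.30, 0.12, 0.22, 0.15],
            covariance=_cov(0.05),
            weight=0.3,
            outcome_effects={"w36_zscore": -0.18, "bpd": -0.5},
        ),
        ClusterArchetype(
            name="parenteral-intensive",
            mean_proportions=[0.35, 0.13, 0.12, 0.18, 0.70, 0.55],
            covariance=_cov(0.05),
            weight=0.2,
            admission_shift={"ga_weeks": -3.0, "bw_zscore": -0.15},
            outcome_effects={"w36_zscore": -0.30, "bpd": 1.0,
                             "mortality": 1.5, "severe_nec": 1.2},
        ),
    ]


@dataclass
class CohortSpec:
    """Configuration for one synthetic cohort draw."""

    n_infants: int = 3000
    archetypes: list = field(default_factory=default_archetypes)
    birth_year_range: tuple = (2012, 2017)
    region_probabilities: tuple = (0.30, 0.27, 0.20, 0.23)
    missingness_rate: float = 0.0
    transfer_fraction: float = 0.35
    los_median: float = 49.0
    los_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_infants < 0:
            raise ConfigurationError("n_infants must be >= 0")
        if not self.archetypes:
            raise ConfigurationError("at least one archetype is required")
        w = sum(a.weight for a in self.archetypes)
        if abs(w - 1.0) > 1e-8:
            raise ConfigurationError(f"archetype weights must sum to 1 (got {w})")
        rp = np.asarray(self.region_probabilities, float)
        if rp.shape != (4,) or abs(rp.sum() - 1.0) > 1e-8 or np.any(rp < 0):
            raise ConfigurationError("region_probabilities must be a 4-vector summing to 1")
        if not 0 <= self.missingness_rate <= 1:
            raise ConfigurationError("missingness_rate must lie in [0,1]")
        if not 0 <= self.transfer_fraction <= 1:
            raise ConfigurationError("transfer_fraction must lie in [0,1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigurationError("birth_year_range must be a non-empty interval")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "archetypes" in d:
            d["archetypes"] = [
                a if isinstance(a, ClusterArchetype) else ClusterArchetype(**a)
                for a in d["archetypes"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Planted truth for a generated cohort: one archetype label per infant,
    the planted day-counts, latent outcome values, and the archetype
    definitions (including planted effect sizes)."""

    labels: pd.Series                 # infant_id -> archetype name
    day_counts: pd.DataFrame          # infant_id x components, plus n_days
    outcomes: pd.DataFrame            # infant_id x latent outcome values
    archetypes: list

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "archetypes": [a.to_dict() for a in self.archetypes],
            "day_counts": self.day_counts.to_dict(orient="index"),
            "outcomes": self.outcomes.where(self.outcomes.notna(), None).to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _empty_cohort():
    episodes = pd.DataFrame(columns=EPISODE_COLUMNS)
    daily = pd.DataFrame(columns=DAILY_COLUMNS)
    truth = GroundTruth(
        labels=pd.Series(dtype=object, name="archetype"),
        day_counts=pd.DataFrame(columns=COMPONENTS + ["n_days"]),
        outcomes=pd.DataFrame(),
        archetypes=[],
    )
    return episodes, daily, truth


def generate_cohort(spec: CohortSpec, reference: LMSReference | None = None):
    """Draw one cohort; deterministic given ``spec.seed``.

    Returns ``(episodes, daily, truth)``: the episodic admission table, the
    daily record table (transfer days split into two partial rows so that
    timestamp-union merging is exercised), and the :class:`GroundTruth`.
    """
    if not isinstance(spec, CohortSpec):
        raise ConfigurationError("spec must be a CohortSpec")
    if spec.n_infants == 0:
        episodes, daily, truth = _empty_cohort()
        truth.archetypes = list(spec.archetypes)
        return episodes, daily, truth

    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = LMSReference.synthetic()
    n = spec.n_infants
    arch_idx = rng.choice(len(spec.archetypes), size=n,
                          p=[a.weight for a in spec.archetypes])

    # --- admission covariates -------------------------------------------
    ga = rng.choice(GA_WEEKS, size=n, p=GA_PROBS).astype(float)
    bw_z = rng.normal(-0.16, 1.0, size=n)
    for k, arch in enumerate(spec.archetypes):
        mask = arch_idx == k
        ga[mask] += arch.admission_shift.get("ga_weeks", 0.0)
        bw_z[mask] += arch.admission_shift.get("bw_zscore", 0.0)
    ga = np.clip(np.round(ga), 22, 31).astype(int)
    sex = rng.binomial(1, 0.46, size=n)                     # 0 boy, 1 girl
    steroids = rng.binomial(1, 0.90, size=n)
    resus = rng.binomial(1, _sigmoid(-2.5 - 0.3 * (ga - 29)))
    apgar1 = np.clip(np.round(rng.normal(6.3 + 0.3 * (ga - 29), 1.8)), 0, 10).astype(int)
    apgar5 = np.clip(apgar1 + np.maximum(np.round(rng.normal(1.8, 1.0, n)), 0), 0, 10).astype(int)
    apgar10 = np.clip(apgar5 + np.maximum(np.round(rng.normal(0.8, 0.8, n)), 0), 0, 10).astype(int)
    imd = rng.integers(1, 11, size=n)
    smoking = rng.binomial(1, 0.13, size=n)
    region = rng.choice(REGIONS, size=n, p=np.asarray(spec.region_probabilities, float))
    birth_year = rng.integers(spec.birth_year_range[0], spec.birth_year_range[1] + 1, size=n)
    birth_doy = rng.integers(0, 365, size=n)
    birth_date = (pd.to_datetime(birth_year.astype(str) + "-01-01")
                  + pd.to_timedelta(birth_doy, unit="D"))

    # --- stay span and outcomes -----------------------------------------
    log_los = rng.normal(np.log(spec.los_median) + 0.15 * (29 - ga), spec.los_sigma)
    span = np.clip(np.round(np.exp(log_los)), 3, 180).astype(int)

    eff = {key: np.array([a.outcome_effects.get(key, 0.0) for a in spec.archetypes])[arch_idx]
           for key in ("mortality", "bpd", "severe_nec", "w36_zscore")}
    mortality = rng.binomial(1, _sigmoid(-3.6 - 0.55 * (ga - 29) + eff["mortality"]))
    span = np.where(mortality == 1, np.maximum(2, np.round(0.25 * span)).astype(int), span)
    n_days = span + 1                                        # records on days 0..span
    bpd_flag = rng.binomial(1, _sigmoid(-1.2 - 0.4 * (ga - 29) + eff["bpd"]))
    severe_nec = rng.binomial(1, _sigmoid(-3.9 - 0.25 * (ga - 29) + eff["severe_nec"]))
    w36_latent = (-1.45 + 0.72 * bw_z + 0.05 * (ga - 29) + eff["w36_zscore"]
                  + rng.normal(0.0, 0.5, size=n))
    d36 = 36 * 7 - 7 * ga                                    # postnatal day at 36w PMA
    died_before_36 = (mortality == 1) & (span < d36)
    in_care_at_36 = (~died_before_36.astype(bool)) & (d36 <= span)

    # --- planted proportions -> day-counts ------------------------------
    props = np.empty((n, 6))
    for k, arch in enumerate(spec.archetypes):
        mask = arch_idx == k
        m = int(mask.sum())
        if m:
            props[mask] = rng.multivariate_normal(
                arch.mean_proportions, arch.covariance, size=m, method="svd")
    props = np.clip(props, 0.0, 1.0)
    counts = np.clip(np.round(props * n_days[:, None]), 0, n_days[:, None]).astype(int)

    # --- realise day sequences ------------------------------------------
    total_rows = int(n_days.sum())
    offsets = np.concatenate([[0], np.cumsum(n_days)])
    day_index = np.concatenate([np.arange(t) for t in n_days])
    infant_row = np.repeat(np.arange(n), n_days)
    comp_values = {c: np.zeros(total_rows, dtype=float) for c in COMPONENTS}
    for i in range(n):
        t = n_days[i]
        u = day_index[offsets[i]:offsets[i] + t] / max(t - 1, 1)
        for j, comp in enumerate(COMPONENTS):
            c = counts[i, j]
            if c == 0:
                continue
            if c == t:
                chosen = np.arange(t)
            else:
                w = np.exp(TIMELINE_RATES[comp] * u)
                chosen = rng.choice(t, size=c, replace=False, p=w / w.sum())
            comp_values[comp][offsets[i] + chosen] = 1.0

    mm_col = comp_values["MM"]
    mm_at_discharge = np.zeros(n, dtype=int)
    for i in range(n):
        last_two = slice(offsets[i] + max(n_days[i] - 2, 0), offsets[i] + n_days[i])
        mm_at_discharge[i] = int(mm_col[last_two].max() > 0)

    # --- weights and respiratory support --------------------------------
    z_traj = (bw_z[infant_row]
              + (w36_latent - bw_z)[infant_row] * (day_index / d36[infant_row]))
    core = pd.DataFrame({
        "sex": sex[infant_row], "ga_weeks": ga[infant_row],
        "postnatal_day": day_index,
    })
    ref_table = reference._table.reset_index()
    core = core.merge(ref_table, on=["sex", "ga_weeks", "postnatal_day"], how="left")
    weight = lms_weight(z_traj, core["L"].to_numpy(), core["M"].to_numpy(),
                        core["S"].to_numpy())
    resp = ((day_index <= 3)
            | ((day_index == d36[infant_row]) & (bpd_flag[infant_row] == 1))).astype(float)

    infant_ids = np.array([f"I{i:06d}" for i in range(n)])
    timestamps = birth_date[infant_row] + pd.to_timedelta(day_index, unit="D")
    daily = pd.DataFrame({"infant_id": infant_ids[infant_row], "timestamp": timestamps})
    for c in COMPONENTS:
        daily[c] = comp_values[c]
    daily["weight_g"] = weight
    daily["respiratory_support"] = resp

    # --- episodes, with transfer-day record splitting -------------------
    has_transfer = (rng.random(n) < spec.transfer_fraction) & (span >= 3)
    transfer_day = np.where(has_transfer, rng.integers(1, np.maximum(span, 2)), -1)

    ep_rows = []
    for i in range(n):
        dest = "death" if mortality[i] == 1 else "home"
        ep_rows.append((infant_ids[i], birth_date[i], birth_date[i], ga[i],
                        None, sex[i], steroids[i], resus[i], apgar1[i], apgar5[i],
                        apgar10[i], imd[i], smoking[i], region[i],
                        None if has_transfer[i] else dest,
                        None if has_transfer[i] else severe_nec[i]))
        if has_transfer[i]:
            t2 = birth_date[i] + pd.Timedelta(days=int(transfer_day[i]))
            ep_rows.append((infant_ids[i], t2, None, None, None, None, None, None,
                            None, None, None, None, None, region[i], dest, severe_nec[i]))
    episodes = pd.DataFrame(ep_rows, columns=EPISODE_COLUMNS)
    bw_g = np.array([reference.weight(bw_z[i], sex[i], ga[i], 0) for i in range(n)])
    first_ep = ~episodes.duplicated("infant_id")
    episodes.loc[first_ep, "birth_weight_g"] = bw_g

    # split the transfer-day daily row into two partial rows (union-mergeable)
    if has_transfer.any():
        tmask = np.zeros(total_rows, dtype=bool)
        for i in np.flatnonzero(has_transfer):
            tmask[offsets[i] + transfer_day[i]] = True
        split_a = daily[tmask].copy()
        split_b = daily[tmask].copy()
        split_a[["PN", "GE", "weight_g", "respiratory_support"]] = np.nan
        split_b[["MM", "HDM", "BMF", "FM"]] = np.nan
        daily = pd.concat([daily[~tmask], split_a, split_b], ignore_index=True)
        daily = daily.sort_values(["infant_id", "timestamp"], kind="stable",
                                  ignore_index=True)

    if spec.missingness_rate > 0:
        daily = inject_missingness(daily, spec.missingness_rate,
                                   seed=int(rng.integers(0, 2 ** 31)))

    truth = GroundTruth(
        labels=pd.Series([spec.archetypes[k].name for k in arch_idx],
                         index=infant_ids, name="archetype"),
        day_counts=pd.DataFrame(counts, index=infant_ids, columns=COMPONENTS)
                     .assign(n_days=n_days, los=span),
        outcomes=pd.DataFrame({
            "mortality": mortality, "severe_nec": severe_nec,
            "bpd": np.where(died_before_36, np.nan,
                            np.where(d36 <= span, bpd_flag, 0.0)),
            "mm_at_discharge": mm_at_discharge, "los": span,
            "w36_zscore": np.where(in_care_at_36, w36_latent, np.nan),
            "bw_zscore": bw_z, "in_care_at_36": in_care_at_36.astype(int),
        }, index=infant_ids),
        archetypes=list(spec.archetypes),
    )
    return episodes, daily, truth


def inject_missingness(daily: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Independently blank each nutrition field with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ConfigurationError("missingness rate must lie in [0,1]")
    out = daily.copy()
    if rate == 0 or out.empty:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(COMPONENTS))) < rate
    values = out[COMPONENTS].to_numpy(dtype=float)
    values[mask] = np.nan
    out[COMPONENTS] = values
    return out


def write_cohort(episodes, daily, truth, outdir) -> None:
    """Write episodes.csv / daily.csv / truth.json in the curation dialect."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    episodes.to_csv(outdir / "episodes.csv", index=False)
    daily.to_csv(outdir / "daily.csv", index=False)
    truth.to_json(outdir / "truth.json")
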
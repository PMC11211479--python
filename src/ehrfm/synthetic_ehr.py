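"""Two-site synthetic EHR generator with latent-state structure.

The generator emulates the setting of a cross-hospital transfer study:
two hospitals with overlapping but frequency-shifted code vocabularies
(a pediatric-like site ``A`` and an adult-like site ``B``), inpatient
admissions with variable length of stay, numeric lab events that can cross
clinically defined outcome thresholds, skewed outcome prevalences, and a
latent daily patient-state process that makes next-code pretraining
informative about outcomes.

Mechanics
---------
Each patient carries a latent severity state in ``{0..n_states-1}``
("stable" → "critical").  A patient's first-admission state doubles as a
frailty variable that also drives their pre-admission outpatient history,
so histories observed *before* the prediction time are predictive of
in-admission outcomes.  During an admission the state evolves daily by a
row-stochastic transition matrix; each admitted day emits Poisson-many
coded events from a state- and site-conditional categorical distribution
plus Bernoulli-sampled lab measurements with state-dependent Gaussian
values.  Each day ends with a death hazard, then a discharge hazard
(zero on the admission day), then a state transition.  Discharged
patients are readmitted within 3–30 days with a probability conditioned
on their final state.

Outcomes are *emergent*: mortality from death hazards, long stays from
discharge hazards, lab outcomes from Gaussian threshold crossings,
readmission from the post-discharge Bernoulli.  Every outcome probability
has a closed form obtained by iterating the day-level Markov recursion
(:func:`analytic_prevalences`), which downstream tests use as the oracle.

Timing conventions: admissions start at 12:00 of day 0 and end at 12:00
(discharge) or 18:00 (death) of the final day, so length of stay in days
equals the final day index exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .timeline_store import (
    MINUTES_PER_DAY,
    AdmissionRecord,
    CodedEvent,
    PatientTimeline,
)

LAB_CODES = ("LAB/GLU", "LAB/NA", "LAB/K", "LAB/HGB", "LAB/PLT")

#: (threshold, direction) per lab code; direction "<" fires below, ">" above
LAB_THRESHOLDS = {
    "LAB/GLU": (3.0, "<"),
    "LAB/NA": (125.0, "<"),
    "LAB/K": (7.0, ">"),
    "LAB/HGB": (70.0, "<"),
    "LAB/PLT": (50.0, "<"),
}


class ConfigError(ValueError):
    """A probability vector or hazard in the configuration is invalid."""


def _check_stochastic(v: np.ndarray, name: str) -> None:
    if np.any(v < -1e-12) or abs(float(np.sum(v)) - 1.0) > 1e-9:
        raise ConfigError(f"{name} is not a probability vector: {v}")


@dataclass
class LatentStateModel:
    """Shared day-level severity dynamics (site-independent parts)."""

    n_states: int = 4
    #: daily row-stochastic transition matrix between severity states
    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.90, 0.080, 0.015, 0.005],
                [0.25, 0.600, 0.120, 0.030],
                [0.05, 0.250, 0.600, 0.100],
                [0.02, 0.080, 0.300, 0.600],
            ]
        )
    )
    #: per-state per-day probability the stay ends in discharge (0 on day 0)
    discharge_hazard: np.ndarray = field(
        default_factory=lambda: np.array([0.45, 0.25, 0.10, 0.03])
    )
    #: per-state per-day probability of in-hospital death
    death_hazard: np.ndarray = field(
        default_factory=lambda: np.array([0.0005, 0.002, 0.010, 0.055])
    )
    #: per-state Poisson rate of general (non-lab) codes per admitted day
    event_rate: np.ndarray = field(default_factory=lambda: np.array([3.0, 5.0, 7.0, 9.0]))
    #: per-state probability a given lab is measured on a given admitted day
    lab_measure_prob: np.ndarray = field(
        default_factory=lambda: np.array(
            [  # GLU   NA    K     HGB   PLT
                [0.50, 0.40, 0.40, 0.35, 0.35],
                [0.60, 0.50, 0.50, 0.45, 0.45],
                [0.75, 0.65, 0.65, 0.60, 0.60],
                [0.90, 0.80, 0.80, 0.75, 0.75],
            ]
        )
    )
    #: per-state Gaussian mean of each lab value (units of the lab)
    lab_mean: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [5.2, 139.0, 4.1, 125.0, 260.0],
                [4.8, 137.0, 4.4, 115.0, 220.0],
                [4.2, 134.0, 4.9, 100.0, 160.0],
                [3.6, 131.0, 5.5, 88.0, 110.0],
            ]
        )
    )
    lab_sd: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.8, 3.0, 0.5, 12.0, 60.0],
                [0.9, 4.0, 0.6, 14.0, 70.0],
                [1.0, 5.0, 0.8, 16.0, 80.0],
                [1.1, 6.0, 1.0, 18.0, 70.0],
            ]
        )
    )
    #: per-state probability of a 30-day readmission after live discharge
    readmission_prob: np.ndarray = field(
        default_factory=lambda: np.array([0.03, 0.06, 0.12, 0.25])
    )
    max_los_days: int = 45  # forced discharge cap

    def validate(self) -> None:
        for i, row in enumerate(np.atleast_2d(self.transition)):
            _check_stochastic(np.asarray(row), f"transition row {i}")
        for name in ("discharge_hazard", "death_hazard", "readmission_prob"):
            h = np.asarray(getattr(self, name))
            if np.any(h < 0) or np.any(h > 1):
                raise ConfigError(f"{name} outside [0,1]")
        if np.any(np.asarray(self.lab_measure_prob) < 0) or np.any(
            np.asarray(self.lab_measure_prob) > 1
        ):
            raise ConfigError("lab_measure_prob outside [0,1]")

    def lab_cross_prob(self) -> np.ndarray:
        """P(measured value crosses the outcome threshold) per (state, lab)."""
        out = np.empty((self.n_states, len(LAB_CODES)))
        for j, code in enumerate(LAB_CODES):
            thr, direction = LAB_THRESHOLDS[code]
            z = (thr - self.lab_mean[:, j]) / self.lab_sd[:, j]
            out[:, j] = norm.cdf(z) if direction == "<" else norm.sf(z)
        return out


@dataclass
class SiteProfile:
    """Per-site population and coding characteristics."""

    site_id: str
    n_patients: int = 2000
    #: distribution of the admission-time severity state (also frailty)
    initial_dist: np.ndarray = field(
        default_factory=lambda: np.array([0.55, 0.25, 0.15, 0.05])
    )
    #: age in days is min + (max-min) * Beta(a, b)
    age_beta: tuple[float, float] = (1.2, 1.8)
    age_range_days: tuple[float, float] = (40.0, 17.0 * 365.25)
    #: fraction of patients below the site's age floor (exercises exclusion)
    underage_frac: float = 0.03
    underage_range_days: tuple[float, float] = (3.0, 25.0)
    male_frac: float = 0.54
    min_age_days: float = 28.0  # eligibility floor used downstream
    #: multiplicative log-frequency tilt applied to shared codes
    freq_tilt: float = 0.8
    #: shift added to the severity affinity of every 4th shared code,
    #: making part of the coding semantics site-specific
    affinity_shift: float = 0.0
    #: if true, every 6th shared code has its severity affinity mirrored
    #: at this site — the same code signals the opposite acuity, the kind
    #: of cross-hospital coding variation an external model misreads
    reverse_semantics: bool = False
    outpatient_event_mean: float = 30.0
    outpatient_lab_mean: float = 3.0

    def validate(self) -> None:
        _check_stochastic(np.asarray(self.initial_dist), f"{self.site_id} initial_dist")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")


def default_site_profiles() -> tuple[SiteProfile, SiteProfile]:
    """Pediatric-like site A and adult-like site B (shifted case mix)."""
    a = SiteProfile(site_id="A")
    b = SiteProfile(
        site_id="B",
        initial_dist=np.array([0.30, 0.30, 0.25, 0.15]),
        age_beta=(1.3, 1.5),
        age_range_days=(18.0 * 365.25, 85.0 * 365.25),
        underage_range_days=(14.0 * 365.25, 17.9 * 365.25),
        male_frac=0.40,
        min_age_days=18.0 * 365.25,
        affinity_shift=1.0,
        reverse_semantics=True,
    )
    return a, b


@dataclass
class SynthConfig:
    seed: int = 0
    sites: tuple[SiteProfile, SiteProfile] = field(default_factory=default_site_profiles)
    latent: LatentStateModel = field(default_factory=LatentStateModel)
    n_core_codes: int = 64
    n_exclusive_codes: int = 8  # per site

    def validate(self) -> None:
        self.latent.validate()
        for s in self.sites:
            s.validate()

    def site(self, site_id: str) -> SiteProfile:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    # -- vocabulary construction -------------------------------------------

    def general_codes(self, site_id: str) -> list[str]:
        """Shared core codes plus this site's exclusive block."""
        fams = ("DX", "RX", "PX")
        core = [f"{fams[i % 3]}/{i:03d}" for i in range(self.n_core_codes)]
        idx = [s.site_id for s in self.sites].index(site_id)
        excl = [f"X{site_id}/{i:03d}" for i in range(self.n_exclusive_codes)]
        del idx
        return core + excl

    def emission_matrix(self, site_id: str) -> tuple[list[str], np.ndarray]:
        """State-conditional categorical over this site's general codes.

        Each code carries a severity affinity in [0, n_states-1]; a state
        emits codes near its own severity (softmax of negative distance).
        Shared codes get a site-specific log-frequency tilt, and at sites
        with ``affinity_shift`` every 4th shared code has its affinity
        displaced — coding semantics the other site's model never saw.
        """
        prof = self.site(site_id)
        codes = self.general_codes(site_id)
        n = len(codes)
        ns = self.latent.n_states
        affinity = np.linspace(0.0, ns - 1.0, n)
        affinity = affinity.copy()
        if prof.affinity_shift:
            shifted = np.arange(n) % 4 == 0
            affinity[shifted] = np.clip(
                affinity[shifted] + prof.affinity_shift, 0.0, ns - 1.0
            )
        if prof.reverse_semantics:
            mirrored = (np.arange(n) % 6 == 1) & (np.arange(n) < self.n_core_codes)
            affinity[mirrored] = (ns - 1.0) - affinity[mirrored]
        # alternating-sign frequency tilt on the shared core, flipped for
        # the second site so the two marginals diverge
        sign = 1.0 if site_id == self.sites[0].site_id else -1.0
        tilt = np.zeros(n)
        half = self.n_core_codes // 2
        tilt[:half] = sign * prof.freq_tilt
        tilt[half : self.n_core_codes] = -sign * prof.freq_tilt
        weights = np.empty((ns, n))
        for s in range(ns):
            weights[s] = np.exp(-np.abs(affinity - s) / 0.6 + tilt)
        weights /= weights.sum(axis=1, keepdims=True)
        return codes, weights


# ---------------------------------------------------------------------------
# Structured-text configuration


def config_to_yaml(config: SynthConfig) -> str:
    """Serialize a configuration to YAML (arrays become nested lists)."""
    import yaml

    def clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if hasattr(obj, "__dataclass_fields__"):
            return {k: clean(getattr(obj, k)) for k in obj.__dataclass_fields__}
        return obj

    return yaml.safe_dump(clean(config), sort_keys=True)


def config_from_yaml(text: str) -> SynthConfig:
    """Parse and validate a YAML configuration produced by
    :func:`config_to_yaml` (unknown keys are rejected)."""
    import yaml

    raw = yaml.safe_load(text)

    def build(cls, d):
        fields = cls.__dataclass_fields__
        unknown = set(d) - set(fields)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list) and v and isinstance(v[0], (int, float, list)):
                kwargs[k] = np.asarray(v, dtype=float)
            elif isinstance(v, list):
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    sites = tuple(build(SiteProfile, s) for s in raw.pop("sites"))
    latent_d = raw.pop("latent")
    latent_d["n_states"] = int(latent_d["n_states"])
    latent_d["max_los_days"] = int(latent_d["max_los_days"])
    latent = build(LatentStateModel, latent_d)
    cfg = SynthConfig(sites=sites, latent=latent, **raw)
    # tuples serialized as lists need their scalar types back
    for s in cfg.sites:
        s.age_beta = tuple(float(v) for v in np.asarray(s.age_beta).ravel())
        s.age_range_days = tuple(float(v) for v in np.asarray(s.age_range_days).ravel())
        s.underage_range_days = tuple(
            float(v) for v in np.asarray(s.underage_range_days).ravel()
        )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Generation


def _simulate_admission(
    rng: np.random.Generator,
    cfg: SynthConfig,
    site: SiteProfile,
    codes: list[str],
    emis: np.ndarray,
    start_day: int,
    s0: int,
) -> tuple[AdmissionRecord, list[CodedEvent], int, bool]:
    """Run one admission; returns (record, events, last_state, died)."""
    lat = cfg.latent
    s = s0
    events: list[CodedEvent] = []
    day = 0
    while True:
        base = (start_day + day) * MINUTES_PER_DAY
        # on the admission day itself events start after the 12:00 admission,
        # so they fall inside the admission→prediction-time exclusion window
        gen_start = 13 * 60 if day == 0 else 8 * 60
        lab_start = 12 * 60 + 30 if day == 0 else 6 * 60
        n_ev = rng.poisson(lat.event_rate[s])
        if n_ev > 0:
            picks = rng.choice(len(codes), size=n_ev, p=emis[s])
            for j, c in enumerate(picks):
                events.append(
                    CodedEvent(codes[c], base + gen_start + (10 * j) % 180, None, site.site_id)
                )
        measured = rng.random(len(LAB_CODES)) < lat.lab_measure_prob[s]
        for j, code in enumerate(LAB_CODES):
            if measured[j]:
                val = rng.normal(lat.lab_mean[s, j], lat.lab_sd[s, j])
                events.append(CodedEvent(code, base + lab_start + j, float(val), site.site_id))
        if rng.random() < lat.death_hazard[s]:
            t_end = base + 18 * 60
            rec = AdmissionRecord(
                admit_time=start_day * MINUTES_PER_DAY + 12 * 60,
                discharge_time=t_end,
                death_time=t_end,
            )
            return rec, events, s, True
        if (day > 0 and rng.random() < lat.discharge_hazard[s]) or day >= lat.max_los_days:
            rec = AdmissionRecord(
                admit_time=start_day * MINUTES_PER_DAY + 12 * 60,
                discharge_time=base + 12 * 60,
            )
            return rec, events, s, False
        s = int(rng.choice(lat.n_states, p=lat.transition[s]))
        day += 1


def generate_site_population(config: SynthConfig, site_id: str) -> list[PatientTimeline]:
    """Generate one site's patients; byte-identical for a fixed seed."""
    config.validate()
    site = config.site(site_id)
    lat = config.latent
    site_index = [s.site_id for s in config.sites].index(site_id)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919 + site_index]))
    codes, emis = config.emission_matrix(site_id)

    timelines: list[PatientTimeline] = []
    for i in range(site.n_patients):
        pid = f"{site_id}{i:06d}"
        frailty = int(rng.choice(lat.n_states, p=site.initial_dist))
        # admission date somewhere in a 3-year window (days since epoch)
        adm_day = int(rng.integers(18_500, 19_500))
        if rng.random() < site.underage_frac:
            age_days = rng.uniform(*site.underage_range_days)
        else:
            lo, hi = site.age_range_days
            age_days = lo + (hi - lo) * rng.beta(*site.age_beta)
        birth = adm_day * MINUTES_PER_DAY + 12 * 60 - int(age_days * MINUTES_PER_DAY)
        sex = "M" if rng.random() < site.male_frac else "F"

        events: list[CodedEvent] = []
        # outpatient history in the 2 years before admission, emitted from
        # the frailty state: this is what makes pre-admission features
        # informative about in-admission outcomes
        n_out = rng.poisson(site.outpatient_event_mean)
        if n_out > 0:
            days_back = np.sort(rng.integers(3, 730, size=n_out))[::-1]
            picks = rng.choice(len(codes), size=n_out, p=emis[frailty])
            for db, c in zip(days_back, picks):
                t = (adm_day - int(db)) * MINUTES_PER_DAY + 10 * 60
                if t > birth:
                    events.append(CodedEvent(codes[c], t, None, site_id))
        n_outlab = rng.poisson(site.outpatient_lab_mean)
        for _ in range(n_outlab):
            j = int(rng.integers(len(LAB_CODES)))
            db = int(rng.integers(3, 730))
            t = (adm_day - db) * MINUTES_PER_DAY + 11 * 60
            if t > birth:
                val = rng.normal(lat.lab_mean[frailty, j], lat.lab_sd[frailty, j])
                events.append(CodedEvent(LAB_CODES[j], t, float(val), site_id))

        admissions: list[AdmissionRecord] = []
        start_day, s0 = adm_day, frailty
        while True:
            rec, ev, s_last, died = _simulate_admission(
                rng, config, site, codes, emis, start_day, s0
            )
            admissions.append(rec)
            events.extend(ev)
            if died:
                break
            if rng.random() < lat.readmission_prob[s_last]:
                gap = int(rng.integers(3, 31))  # within the 30-day window
            elif rng.random() < 0.10:
                gap = int(rng.integers(35, 91))  # later admission, label 0
            else:
                break
            start_day = rec.discharge_time // MINUTES_PER_DAY + gap
            s0 = int(rng.choice(lat.n_states, p=site.initial_dist))
            if len(admissions) >= 4:
                break

        timelines.append(
            PatientTimeline(
                patient_id=pid, birth_date=birth, sex=sex, site=site_id,
                events=sorted(events, key=lambda e: e.time), admissions=admissions,
            )
        )
    return timelines


# ---------------------------------------------------------------------------
# Closed-form oracles


def _day_recursion(lat: LatentStateModel, init: np.ndarray):
    """Yield per-day occupancy and end-of-stay flows.

    Returns arrays ``alpha`` (in-hospital-at-start-of-day occupancy,
    shape (D+1, S)), ``death_flow`` and ``discharge_flow`` (probability the
    stay ends that day in each state).
    """
    D = lat.max_los_days
    S = lat.n_states
    alpha = np.zeros((D + 1, S))
    death = np.zeros((D + 1, S))
    disch = np.zeros((D + 1, S))
    alpha[0] = init
    for d in range(D + 1):
        a = alpha[d]
        death[d] = a * lat.death_hazard
        rem = a - death[d]
        q = lat.discharge_hazard if d > 0 else np.zeros(S)
        if d == lat.max_los_days:
            q = np.ones(S)
        disch[d] = rem * q
        rem = rem - disch[d]
        if d < D:
            alpha[d + 1] = rem @ lat.transition
    return alpha, death, disch


def analytic_prevalences(config: SynthConfig, site_id: str) -> dict[str, float]:
    """Exact per-admission outcome prevalences among labeled admissions.

    Conditioning matches the cohort rules: admissions that end (death) on
    the admission day are excluded globally, and for each lab task
    admissions whose first threshold crossing happens on the admission day
    (before the prediction time) are excluded for that task.
    """
    lat = config.latent
    init = np.asarray(config.site(site_id).initial_dist, dtype=float)
    alpha, death, disch = _day_recursion(lat, init)
    p_death_day0 = float(death[0].sum())
    p_incl = 1.0 - p_death_day0

    out: dict[str, float] = {}
    out["mortality"] = float(death[1:].sum()) / p_incl
    out["long_los"] = float(alpha[7].sum()) / p_incl
    out["readmission_30d"] = float((disch * lat.readmission_prob).sum()) / p_incl

    cross = lat.lab_cross_prob() * lat.lab_measure_prob  # per (state, lab) per day
    task_names = ("hypoglycemia", "hyponatremia", "hyperkalemia", "anemia", "thrombocytopenia")
    lab_order = ("LAB/GLU", "LAB/NA", "LAB/K", "LAB/HGB", "LAB/PLT")
    name_of = dict(zip(lab_order, ("hypoglycemia", "hyponatremia", "hyperkalemia",
                                   "anemia", "thrombocytopenia")))
    del task_names
    for j, code in enumerate(lab_order):
        x = cross[:, j]
        D, S = lat.max_los_days, lat.n_states
        gamma = np.zeros((D + 1, S))  # in hospital, no crossing on days < d
        gamma[0] = init
        p_label = 0.0
        p_task_excl = float((init * x).sum())  # crossing on day 0
        # death on day 0 without a crossing is the global exclusion
        p_task_excl += float((init * (1 - x) * lat.death_hazard).sum())
        for d in range(D + 1):
            g = gamma[d]
            if d >= 1:
                p_label += float((g * x).sum())
            rem = g * (1 - x) * (1 - lat.death_hazard)
            q = lat.discharge_hazard if d > 0 else np.zeros(S)
            if d == D:
                q = np.ones(S)
            rem = rem * (1 - q)
            if d < D:
                gamma[d + 1] = rem @ lat.transition
        out[name_of[code]] = p_label / (1.0 - p_task_excl)
    return out


def token_state_occupancy(config: SynthConfig, site_id: str) -> np.ndarray:
    """Long-run share of emitted in-admission general codes per state."""
    lat = config.latent
    init = np.asarray(config.site(site_id).initial_dist, dtype=float)
    alpha, _, _ = _day_recursion(lat, init)
    w = (alpha * lat.event_rate).sum(axis=0)
    return w / w.sum()


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def code_entropies(config: SynthConfig, site_id: str) -> tuple[float, float]:
    """(unigram entropy, conditional entropy given latent state), in nats.

    The strict gap between the two is what guarantees that next-code
    pretraining has learnable signal on this corpus.
    """
    _, emis = config.emission_matrix(site_id)
    w = token_state_occupancy(config, site_id)
    marginal = w @ emis
    h_uni = _entropy(marginal)
    h_cond = float(sum(w[s] * _entropy(emis[s]) for s in range(len(w))))
    return h_uni, h_cond


def site_marginal(config: SynthConfig, site_id: str) -> dict[str, float]:
    """Analytic marginal distribution over general codes at a site."""
    codes, emis = config.emission_matrix(site_id)
    w = token_state_occupancy(config, site_id)
    return dict(zip(codes, w @ emis))


def total_variation(p: dict[str, float], q: dict[str, float]) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# Simple first-order Markov token corpus (pretraining oracle fixture)


def markov_entropies(P: np.ndarray, pi: np.ndarray | None = None) -> tuple[float, float]:
    """(unigram entropy of the stationary law, conditional entropy) in nats."""
    P = np.asarray(P, dtype=float)
    if pi is None:
        w, v = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = pi / pi.sum()
    else:
        pi = np.asarray(pi, dtype=float)
    h1 = _entropy(pi)
    hc = float(sum(pi[i] * _entropy(P[i]) for i in range(len(pi))))
    return h1, hc


def markov_token_corpus(
    n_seq: int, seq_len: int, P: np.ndarray, seed: int, pi: np.ndarray | None = None
) -> list[list[str]]:
    """Sequences of codes ``"M/<i>"`` from a first-order Markov chain."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if pi is None:
        pi = markov_stationary(P)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    out = []
    for _ in range(n_seq):
        s = int(rng.choice(n, p=pi))
        seq = [s]
        u = rng.random(seq_len - 1)
        for t in range(seq_len - 1):
            s = int(np.searchsorted(cum[s], u[t]))
            seq.append(s)
        out.append([f"M/{i}" for i in seq])
    return out


def markov_stationary(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Corpus summary


def summarize_corpus(timelines: Sequence[PatientTimeline]) -> dict:
    """Per-site code marginals, events/patient, and label prevalences."""
    if not timelines:
        raise ValueError("empty corpus")
    by_site: dict[str, list[PatientTimeline]] = {}
    for tl in timelines:
        by_site.setdefault(tl.site, []).append(tl)
    summary: dict = {"sites": {}}
    for site_id, tls in sorted(by_site.items()):
        counts: dict[str, int] = {}
        n_events = 0
        for tl in tls:
            for e in tl.events:
                counts[e.code] = counts.get(e.code, 0) + 1
                n_events += 1
        total = max(1, sum(counts.values()))
        marginal = {c: k / total for c, k in sorted(counts.items())}
        summary["sites"][site_id] = {
            "n_patients": len(tls),
            "events_per_patient": n_events / len(tls),
            "code_marginal": marginal,
            "prevalence": _empirical_prevalences(tls),
        }
    return summary


def _empirical_prevalences(timelines: Sequence[PatientTimeline]) -> dict[str, float]:
    from .cohort_tasks import TASKS, build_inpatient_cohort, label_task

    cohort = build_inpatient_cohort(timelines, min_age_days=0.0, seed=0)
    out = {}
    for name, spec in TASKS.items():
        examples = label_task(cohort, spec, timelines)
        out[name] = (
            float(np.mean([ex.label for ex in examples])) if examples else float("nan")
        )
    return out
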
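"""Synthetic EMR cohort generator.

Emulates the statistical structure the risk-scoring pipeline assumes: a
mental-health cohort of patients with one or more suicide-risk assessments,
a minority "risk" group (patients with an attempt in the 90-day follow-up),
and pre-assessment diagnosis histories in which the risk group carries
stochastically more physical illness, most visibly in the recent past.

Count model
-----------
Hospital diagnosis codes arrive in batches: an admission (episode) generates
one or more codes on the same date.  The generator mirrors that.  Each
patient carries a gamma frailty g (mean 1, shape k).  Episodes over the full
48-month look-back are Poisson(g * e5); episode dates follow a
piecewise-constant recency profile over the five window segments so the
expected episode count inside window tau is g * e_tau.  Every episode emits
1 + NegativeBinomial(a, mean c-1) codes (mean c, overdispersed), spread
across the 18 chapter headings by fixed group-specific weights.

The shared frailty correlates counts across headings and windows; the
episode/batch split decouples *whether* a window holds any history (episode
process) from *how many* codes it holds (batch sizes).  Both degrees of
freedom are needed: the "paper-like" preset calibrates, at run time from the
packaged fixture tables, the per-window episode means so every no-history
fraction is matched exactly in expectation, and (k, a, c) by least squares
so every total-count bin mass is matched closely; heading weights come from
the 48-month per-heading prevalences.  Use :func:`calibration_report` to
measure, rather than assume, the fit of a simulated cohort.

Clinical ratings (0-4) are drawn from group-conditional discretized-normal
distributions whose separation is solved numerically so the exact
(tie-corrected) AUC between the two groups equals a configurable target.
"""

from __future__ import annotations

import datetime as _dt
import functools
import logging
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import chapters
from .chapters import HEADINGS, N_HEADINGS, N_WINDOWS, WINDOW_DAYS

logger = logging.getLogger(__name__)

HORIZON_DAYS = WINDOW_DAYS[N_WINDOWS]  # 1460

#: Control-group marginal distribution of the 0-4 clinical rating; ~8% of
#: assessments get an overall rating of 0, matching a cohort where ~92% have
#: a positive rating.
CONTROL_CLINICAL_BASE = np.array([0.08, 0.25, 0.34, 0.23, 0.10])

#: Mean count of excluded-chapter codes (V mental, XVI perinatal, XVII
#: congenital) per patient over the full horizon, and their split.  A
#: mental-health cohort is dense in chapter V; these codes exist purely to
#: exercise the featurizer's exclusion filter.
EXCLUDED_MEAN_DEFAULT = 3.0
_EXCLUDED_SPLIT = {"F": 0.90, "P": 0.05, "Q": 0.05}


@dataclass(frozen=True)
class GroupParams:
    """Diagnosis-process parameters for one group (control or risk).

    ``episode_means`` are the cumulative expected episode counts e_tau inside
    windows tau = 1..5 (increasing; e_5 covers the full 48-month horizon).
    ``codes_mean``/``codes_dispersion`` parameterize the >= 1 codes emitted
    per episode; ``heading_weights`` spread codes across the 18 headings.
    """

    frailty_shape: float
    episode_means: tuple[float, ...]
    codes_mean: float
    codes_dispersion: float
    heading_weights: tuple[float, ...]
    excluded_mean: float = EXCLUDED_MEAN_DEFAULT

    def __post_init__(self) -> None:
        if self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be positive")
        e = self.episode_means
        if len(e) != N_WINDOWS or e[0] <= 0 or any(b < a for a, b in zip(e, e[1:])):
            raise ValueError("episode_means must be 5 positive non-decreasing values")
        if self.codes_mean < 1.0:
            raise ValueError("codes_mean must be >= 1 (every episode emits a code)")
        if self.codes_dispersion <= 0:
            raise ValueError("codes_dispersion must be positive")
        w = np.asarray(self.heading_weights)
        if w.shape != (N_HEADINGS,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("heading_weights must be 18 non-negative weights")
        if self.excluded_mean < 0:
            raise ValueError("excluded_mean must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_assessments: int = 16858
    risk_prevalence: float = 2072 / 16858
    clinical_auc: float = 0.56
    control: GroupParams | None = None
    risk: GroupParams | None = None
    mean_assessments_per_patient: float = 16858 / 7399
    study_start: _dt.date = _dt.date(2009, 4, 1)
    study_end: _dt.date = _dt.date(2012, 3, 31)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_assessments < 2:
            raise ValueError("n_assessments must be at least 2")
        if not (0.0 < self.risk_prevalence < 1.0):
            raise ValueError("risk_prevalence must lie in (0, 1)")
        if self.clinical_auc >= 1.0:
            raise ValueError(
                f"clinical discrimination target {self.clinical_auc} is infeasible (must be < 1)"
            )
        if self.clinical_auc < 0.5:
            raise ValueError("clinical discrimination target must be >= 0.5")
        if self.mean_assessments_per_patient < 1.0:
            raise ValueError("mean_assessments_per_patient must be >= 1")


@dataclass
class Cohort:
    """Assessments + diagnoses tables, as written to / read from CSV.

    ``assessments`` columns: assessment_id, patient_id, assessment_date,
    clinical_score, outcome.  ``diagnoses`` columns: patient_id,
    diagnosis_date, icd10_code.  ``outcome`` equals the ground-truth group
    label (1 = risk).
    """

    assessments: pd.DataFrame
    diagnoses: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.assessments["outcome"].to_numpy()


# ---------------------------------------------------------------------------
# fixture-driven calibration
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference-table fixture (``table1_counts`` or ``table2_counts``)."""
    path = resources.files("icdrisk").joinpath(f"fixtures/{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def _codes_per_episode_pmf(a: float, mean: float, upto: int) -> np.ndarray:
    """pmf of the batch size C = 1 + NB(a, mean-1) on 0..upto (zero at 0)."""
    pmf = np.zeros(upto + 1)
    pmf[1:] = stats.nbinom(a, a / (a + mean - 1.0)).pmf(np.arange(upto))
    return pmf


def _compound_bin_masses(k: float, e: float, a: float, cmean: float) -> np.ndarray:
    """Masses of the six total-count bins for S = sum of C_i over N episodes.

    N ~ NB(shape k, mean e) (gamma-frailty Poisson), C >= 1.  The pmf of S up
    to 20 comes from the Panjer recursion for the negative-binomial class;
    the top bin is the complement.
    """
    q = k / (k + e)
    pa, pb = 1.0 - q, (k - 1.0) * (1.0 - q)
    fc = _codes_per_episode_pmf(a, cmean, 20)
    fs = np.zeros(21)
    fs[0] = q**k
    for s in range(1, 21):
        j = np.arange(1, s + 1)
        fs[s] = np.sum((pa + pb * j / s) * fc[j] * fs[s - j])
    cum = np.cumsum(fs)
    return np.array(
        [fs[0], cum[2] - cum[0], cum[5] - cum[2], cum[10] - cum[5],
         cum[20] - cum[10], 1.0 - cum[20]]
    )


def expected_bin_masses(params: GroupParams) -> np.ndarray:
    """Expected (5, 6) total-count bin masses per window under ``params``."""
    return np.array(
        [
            _compound_bin_masses(
                params.frailty_shape, e, params.codes_dispersion, params.codes_mean
            )
            for e in params.episode_means
        ]
    )


def _calibrate_group(group: str, table1: pd.DataFrame, table2: pd.DataFrame) -> GroupParams:
    t1g = table1[table1["group"] == group]
    group_total = t1g.query("window == 1")["count"].sum()
    targets = np.array(
        [
            t1g.query("window == @tau")
            .set_index("bin")
            .loc[list(chapters.TOTAL_COUNT_BINS), "count"]
            .to_numpy()
            / group_total
            for tau in range(1, 6)
        ]
    )
    z = targets[:, 0]  # no-history fraction per window

    def episode_means(k: float) -> np.ndarray:
        # exact: P(no episode in window tau) = (k/(k+e_tau))^k = z_tau
        return k * (z ** (-1.0 / k) - 1.0)

    def objective(x: np.ndarray) -> float:
        k, a, cm = np.exp(x)
        cm += 1.0
        e = episode_means(k)
        dev = 0.0
        for t in range(5):
            dev += np.sum(
                (_compound_bin_masses(k, e[t], a, cm)[1:] - targets[t][1:]) ** 2
            )
        return float(dev)

    best = None
    for x0 in ([0.0, 0.0, 0.7], [-1.0, 0.5, 1.2], [0.5, -0.5, 0.3]):
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": 600, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    k, a, cmean = np.exp(best.x)
    cmean += 1.0

    prev = (
        table2.query("window == 5 and group == @group")
        .sort_values("heading_index")["percent"]
        .to_numpy()
        / 100.0
    )
    weights = -np.log1p(-prev)  # Poisson-implied intensity as a weight proxy
    weights = weights / weights.sum()
    return GroupParams(
        frailty_shape=float(k),
        episode_means=tuple(float(x) for x in episode_means(k)),
        codes_mean=float(cmean),
        codes_dispersion=float(a),
        heading_weights=tuple(float(w) for w in weights),
    )


@functools.lru_cache(maxsize=1)
def _calibrated_groups() -> tuple[GroupParams, GroupParams]:
    table1 = load_fixture("table1_counts")
    table2 = load_fixture("table2_counts")
    return (
        _calibrate_group("control", table1, table2),
        _calibrate_group("risk", table1, table2),
    )


def calibrate_preset(seed: int = 0, n_assessments: int = 16858) -> GeneratorConfig:
    """The "paper-like" preset, calibrated from the packaged fixture tables."""
    control, risk = _calibrated_groups()
    return GeneratorConfig(
        seed=seed, n_assessments=n_assessments, control=control, risk=risk
    )


def null_preset(seed: int = 0, n_assessments: int = 5000) -> GeneratorConfig:
    """A no-signal cohort: both groups share the control diagnosis process
    and the clinical rating carries no information (AUC target 0.5)."""
    base = calibrate_preset(seed=seed, n_assessments=n_assessments)
    return replace(base, risk=base.control, clinical_auc=0.5)


# ---------------------------------------------------------------------------
# clinical-rating model
# ---------------------------------------------------------------------------

def _discrete_auc(p_risk: np.ndarray, p_control: np.ndarray) -> float:
    """Exact tie-corrected AUC between two distributions on {0..4}."""
    cum_c = np.concatenate([[0.0], np.cumsum(p_control)])
    return float(np.sum(p_risk * (cum_c[:-1] + 0.5 * p_control)))


def clinical_distributions(target_auc: float) -> tuple[np.ndarray, np.ndarray]:
    """Group-conditional rating distributions achieving ``target_auc`` exactly.

    The control marginal is fixed (:data:`CONTROL_CLINICAL_BASE`); the risk
    marginal is the same latent normal shifted by delta and re-discretized at
    the control cutpoints, with delta solved so the tie-corrected AUC equals
    the target.
    """
    p_c = CONTROL_CLINICAL_BASE
    cuts = stats.norm.ppf(np.cumsum(p_c)[:-1])
    max_auc = _discrete_auc(np.array([0, 0, 0, 0, 1.0]), p_c)
    if not (0.5 <= target_auc < max_auc):
        raise ValueError(
            f"clinical AUC target {target_auc} infeasible for a 0-4 rating "
            f"(achievable range [0.5, {max_auc:.3f}))"
        )

    def risk_probs(delta: float) -> np.ndarray:
        cdf = np.concatenate([[0.0], stats.norm.cdf(cuts - delta), [1.0]])
        return np.diff(cdf)

    if target_auc == 0.5:
        return p_c.copy(), p_c.copy()
    delta = optimize.brentq(
        lambda d: _discrete_auc(risk_probs(d), p_c) - target_auc, 0.0, 12.0
    )
    return risk_probs(delta), p_c.copy()


# ---------------------------------------------------------------------------
# code-string synthesis
# ---------------------------------------------------------------------------

def _codes_in_range(start: tuple[str, int], end: tuple[str, int]) -> list[str]:
    (sl, sn), (el, en) = start, end
    out = []
    for letter in map(chr, range(ord(sl), ord(el) + 1)):
        lo = sn if letter == sl else 0
        hi = en if letter == el else 99
        out.extend(f"{letter}{i:02d}" for i in range(lo, hi + 1))
    return out


_HEADING_CODES: dict[int, np.ndarray] = {
    h.index: np.asarray(
        [c for r in h.code_ranges for c in _codes_in_range(*r)], dtype=object
    )
    for h in HEADINGS
}
_EXCLUDED_CODES = {
    "F": np.asarray(_codes_in_range(("F", 0), ("F", 99)), dtype=object),
    "P": np.asarray(_codes_in_range(("P", 0), ("P", 96)), dtype=object),
    "Q": np.asarray(_codes_in_range(("Q", 0), ("Q", 99)), dtype=object),
}


def _sample_codes(rng: np.random.Generator, pool: np.ndarray, size: int) -> np.ndarray:
    base = rng.choice(pool, size=size)
    dotted = rng.random(size) < 0.3
    suffix = rng.integers(0, 10, size=size)
    return np.asarray(
        [f"{b}.{s}" if d else b for b, s, d in zip(base, suffix, dotted)],
        dtype=object,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_SEGMENT_BOUNDS = np.array([0] + [WINDOW_DAYS[t] for t in range(1, N_WINDOWS + 1)])


def _sample_days_before(
    rng: np.random.Generator, cumulative: np.ndarray, size: int
) -> np.ndarray:
    """Days-before-index following the piecewise recency profile ``cumulative``."""
    seg_mass = np.diff(np.concatenate([[0.0], np.asarray(cumulative)]))
    seg_mass = np.clip(seg_mass, 0.0, None)
    seg_mass = seg_mass / seg_mass.sum()
    seg = rng.choice(N_WINDOWS, size=size, p=seg_mass)
    lo = _SEGMENT_BOUNDS[:-1][seg] + 1
    hi = _SEGMENT_BOUNDS[1:][seg]
    return rng.integers(lo, hi, endpoint=True)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a reproducible synthetic cohort from ``config``.

    Patients receive a group label, a frailty, 1+ assessment dates (extra
    assessments fall within a week before the patient's most recent one) and
    an episode-structured diagnosis history positioned relative to that most
    recent assessment.
    """
    if config.control is None or config.risk is None:
        raise ValueError(
            "config lacks group parameters; start from calibrate_preset() or null_preset()"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_assessments

    # patients and their assessment counts
    est = int(n / config.mean_assessments_per_patient * 1.3) + 10
    sizes = 1 + rng.poisson(config.mean_assessments_per_patient - 1.0, size=est)
    while sizes.sum() < n:
        sizes = np.concatenate(
            [sizes, 1 + rng.poisson(config.mean_assessments_per_patient - 1.0, size=est)]
        )
    n_patients = int(np.searchsorted(np.cumsum(sizes), n) + 1)
    sizes = sizes[:n_patients]
    sizes[-1] -= sizes.sum() - n

    is_risk = rng.random(n_patients) < config.risk_prevalence
    study_days = (config.study_end - config.study_start).days
    index_day = rng.integers(0, study_days + 1, size=n_patients)  # days since study_start
    start_ts = pd.Timestamp(config.study_start)
    patient_ids = np.array([f"P{i:05d}" for i in range(n_patients)], dtype=object)

    # assessment rows; a patient's extra assessments cluster within the week
    # before the index one (repeat assessments within a single admission), so
    # every assessment's look-back windows see essentially the same history
    offsets = rng.integers(0, 8, size=n)
    a_patient, a_day, a_group = [], [], []
    cursor = 0
    for i in range(n_patients):
        offs = sorted(offsets[cursor: cursor + sizes[i] - 1], reverse=True)
        cursor += sizes[i] - 1
        for off in [*offs, 0]:
            a_patient.append(patient_ids[i])
            a_day.append(index_day[i] - off)
            a_group.append(int(is_risk[i]))
    a_group = np.asarray(a_group)
    a_date = (start_ts + pd.to_timedelta(a_day, unit="D")).date

    # clinical ratings
    p_risk, p_control = clinical_distributions(config.clinical_auc)
    clinical = np.empty(n, dtype=np.int64)
    for g, probs in ((0, p_control), (1, p_risk)):
        mask = a_group == g
        clinical[mask] = rng.choice(5, size=int(mask.sum()), p=probs)

    assessments = pd.DataFrame(
        {
            "assessment_id": [f"A{i:06d}" for i in range(n)],
            "patient_id": a_patient,
            "assessment_date": a_date,
            "clinical_score": clinical,
            "outcome": a_group,
        }
    )

    # episode-structured diagnosis events per patient
    params = {0: config.control, 1: config.risk}
    frailty = np.empty(n_patients)
    for g in (0, 1):
        mask = is_risk == (g == 1)
        k = params[g].frailty_shape
        frailty[mask] = rng.gamma(k, 1.0 / k, size=int(mask.sum()))

    d_patient, d_day, d_code = [], [], []
    for g in (0, 1):
        gp = params[g]
        pmask = np.flatnonzero(is_risk == (g == 1))
        e = np.asarray(gp.episode_means)
        profile = e / e[-1]
        n_episodes = rng.poisson(frailty[pmask] * e[-1])
        tot_ep = int(n_episodes.sum())
        if tot_ep:
            ep_patient = np.repeat(pmask, n_episodes)
            ep_day = _sample_days_before(rng, profile, tot_ep)
            a_c = gp.codes_dispersion
            batch = 1 + rng.negative_binomial(
                a_c, a_c / (a_c + gp.codes_mean - 1.0), size=tot_ep
            )
            tot_codes = int(batch.sum())
            code_patient = np.repeat(ep_patient, batch)
            code_day = np.repeat(ep_day, batch)
            heads = rng.choice(
                np.arange(1, N_HEADINGS + 1), size=tot_codes, p=gp.heading_weights
            )
            codes = np.empty(tot_codes, dtype=object)
            for ch in range(1, N_HEADINGS + 1):
                sel = heads == ch
                if sel.any():
                    codes[sel] = _sample_codes(rng, _HEADING_CODES[ch], int(sel.sum()))
            d_patient.append(patient_ids[code_patient])
            d_day.append(index_day[code_patient] - code_day)
            d_code.append(codes)
        # excluded-chapter events to exercise the featurizer's filter
        for letter, share in _EXCLUDED_SPLIT.items():
            n_ev = rng.poisson(frailty[pmask] * gp.excluded_mean * share)
            tot = int(n_ev.sum())
            if tot == 0:
                continue
            rep = np.repeat(pmask, n_ev)
            days = _sample_days_before(rng, profile, tot)
            d_patient.append(patient_ids[rep])
            d_day.append(index_day[rep] - days)
            d_code.append(_sample_codes(rng, _EXCLUDED_CODES[letter], tot))

    if d_patient:
        d_dates = (start_ts + pd.to_timedelta(np.concatenate(d_day), unit="D")).date
        diagnoses = pd.DataFrame(
            {
                "patient_id": np.concatenate(d_patient),
                "diagnosis_date": d_dates,
                "icd10_code": np.concatenate(d_code),
            }
        )
    else:
        diagnoses = pd.DataFrame(columns=["patient_id", "diagnosis_date", "icd10_code"])
    diagnoses = diagnoses.sort_values(
        ["patient_id", "diagnosis_date", "icd10_code"], kind="mergesort"
    ).reset_index(drop=True)
    return Cohort(assessments=assessments, diagnoses=diagnoses)


def calibration_report(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Measure how closely a simulated cohort reproduces the fixture tables.

    Generates a cohort from ``config`` (optionally reseeded), featurizes it,
    and joins its total-count bin distribution against the packaged Table-1
    fixture.  Returns one row per (window, group, bin) with simulated,
    model-expected and reference percentages and absolute differences — the
    approximation quality is reported, never assumed.
    """
    cfg = config if seed is None else replace(config, seed=seed)
    cohort = generate_cohort(cfg)
    F = chapters.frequency_matrix(cohort.assessments, cohort.diagnoses)
    sim = chapters.tabulate_frequency_distribution(F, cohort.labels)
    ref = load_fixture("table1_counts")
    merged = sim.merge(ref, on=["window", "group", "bin"], suffixes=("_sim", "_ref"))
    expected = {
        g: expected_bin_masses(p) * 100.0
        for g, p in (("control", cfg.control), ("risk", cfg.risk))
    }
    bin_pos = {b: i for i, b in enumerate(chapters.TOTAL_COUNT_BINS)}
    merged["percent_model"] = [
        expected[row.group][row.window - 1, bin_pos[row.bin]]
        for row in merged.itertuples()
    ]
    merged["abs_diff_sim"] = (merged["percent_sim"] - merged["percent_ref"]).abs()
    merged["abs_diff_model"] = (merged["percent_model"] - merged["percent_ref"]).abs()
    return merged[
        ["window", "group", "bin", "percent_sim", "percent_model", "percent_ref",
         "abs_diff_sim", "abs_diff_model"]
    ]
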
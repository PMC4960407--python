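"""ICD-10 chapter-heading mapping and time-windowed frequency features.

Raw ICD-10 codes are aggregated into 18 chapter headings: the 22 WHO (2015)
chapters minus chapter V (mental and behavioural disorders, the outcome
domain), minus chapters XVI and XVII (perinatal and congenital, absent in
an adult psychiatric cohort), with chapters VII and VIII (eye; ear) merged
into a single sensory-organ heading.

For each risk assessment, diagnosis events are counted per heading over five
nested look-back windows of 91, 182, 365, 730 and 1460 days (3, 6, 12, 24,
48 months), yielding the frequency matrix ``f_i(tau, ch)`` that every
downstream stage consumes.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned for codes in excluded chapters (V, XVI, XVII) or in
#: letter/number gaps that belong to no chapter.
EXCLUDED = 0

#: Look-back window lengths in days, indexed by tau = 1..5 (3/6/12/24/48 months).
WINDOW_DAYS: dict[int, int] = {1: 91, 2: 182, 3: 365, 4: 730, 5: 1460}

N_WINDOWS = 5
N_HEADINGS = 18

#: Frequency bins used by Table-1 style tabulations (total code count).
TOTAL_COUNT_BINS = ("0", "1-2", "3-5", "6-10", "11-20", ">20")


@dataclass(frozen=True)
class ChapterHeading:
    """One of the 18 aggregated chapter headings.

    ``code_ranges`` holds inclusive (start, end) pairs of letter+number
    positions, e.g. ``(("A", 0), ("B", 99))`` for chapter I.
    """

    index: int
    roman: str
    label: str
    code_ranges: tuple[tuple[tuple[str, int], tuple[str, int]], ...]


def _rng(a: str, b: str) -> tuple[tuple[str, int], tuple[str, int]]:
    return ((a[0], int(a[1:])), (b[0], int(b[1:])))


#: The 18 headings in their fixed order (indices 1..18).  Boundaries follow
#: the WHO 2015 chapter table; D48/D50 and H59/H60 splits are resolved on the
#: numeric part.  Chapters V (F), XVI (P) and XVII (Q) are deliberately absent.
HEADINGS: tuple[ChapterHeading, ...] = (
    ChapterHeading(1, "I", "Certain infectious and parasitic diseases", (_rng("A00", "B99"),)),
    ChapterHeading(2, "II", "Neoplasms", (_rng("C00", "D48"),)),
    ChapterHeading(3, "III", "Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism", (_rng("D50", "D89"),)),
    ChapterHeading(4, "IV", "Endocrine, nutritional and metabolic diseases", (_rng("E00", "E90"),)),
    ChapterHeading(5, "VI", "Diseases of the nervous system", (_rng("G00", "G99"),)),
    ChapterHeading(6, "VII,VIII", "Sensory organ disease", (_rng("H00", "H59"), _rng("H60", "H95"))),
    ChapterHeading(7, "IX", "Diseases of the circulatory system", (_rng("I00", "I99"),)),
    ChapterHeading(8, "X", "Diseases of the respiratory system", (_rng("J00", "J99"),)),
    ChapterHeading(9, "XI", "Diseases of the digestive system", (_rng("K00", "K93"),)),
    ChapterHeading(10, "XII", "Diseases of the skin and subcutaneous tissue", (_rng("L00", "L99"),)),
    ChapterHeading(11, "XIII", "Diseases of the musculoskeletal system and connective tissue", (_rng("M00", "M99"),)),
    ChapterHeading(12, "XIV", "Diseases of the genitourinary system", (_rng("N00", "N99"),)),
    ChapterHeading(13, "XV", "Pregnancy, childbirth and the puerperium", (_rng("O00", "O99"),)),
    ChapterHeading(14, "XVIII", "Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified", (_rng("R00", "R99"),)),
    ChapterHeading(15, "XIX", "Injury, poisoning and certain other consequences of external causes", (_rng("S00", "T98"),)),
    ChapterHeading(16, "XX", "External causes of morbidity and mortality", (_rng("V01", "Y98"),)),
    ChapterHeading(17, "XXI", "Factors influencing health status and contact with health services", (_rng("Z00", "Z99"),)),
    ChapterHeading(18, "XXII", "Codes for special purposes", (_rng("U00", "U99"),)),
)

#: Chapters removed before featurization: V (mental and behavioural disorders,
#: F00-F99), XVI (perinatal, P00-P96) and XVII (congenital, Q00-Q99).
EXCLUDED_LETTERS = frozenset("FPQ")

_CODE_RE = re.compile(r"^([A-Za-z])(\d{2})(?:\.?\d{0,4})?$")

# Flat lookup: letter -> list of (start_num, end_num, heading_index),
# built once from HEADINGS for O(1) vectorizable mapping.
_LETTER_TABLE: dict[str, list[tuple[int, int, int]]] = {}
for _h in HEADINGS:
    for (_sl, _sn), (_el, _en) in _h.code_ranges:
        for _ltr in map(chr, range(ord(_sl), ord(_el) + 1)):
            lo = _sn if _ltr == _sl else 0
            hi = _en if _ltr == _el else 99
            _LETTER_TABLE.setdefault(_ltr, []).append((lo, hi, _h.index))


def map_code_to_heading(code: str) -> int:
    """Map a raw ICD-10 code string to a heading index 1..18 or ``EXCLUDED``.

    Parameters
    ----------
    code
        Raw code such as ``"A09"``, ``"h66.9"`` or ``"Z50.1"``.  A letter
        followed by two digits is required; case and surrounding whitespace
        are ignored.

    Returns
    -------
    int
        Heading index in 1..18, or ``EXCLUDED`` (0) for codes in chapters V,
        XVI, XVII and for syntactically valid codes falling in a gap between
        chapters (the latter case is logged).

    Raises
    ------
    ValueError
        If ``code`` cannot be parsed as an ICD-10 code at all.
    """
    if not isinstance(code, str):
        raise ValueError(f"ICD-10 code must be a string, got {code!r}")
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ValueError(f"unparseable ICD-10 code: {code!r}")
    letter, num = m.group(1).upper(), int(m.group(2))
    if letter in EXCLUDED_LETTERS:
        return EXCLUDED
    for lo, hi, idx in _LETTER_TABLE.get(letter, ()):
        if lo <= num <= hi:
            return idx
    logger.warning("ICD-10 code %r falls outside every chapter range; excluded", code)
    return EXCLUDED


def map_codes(codes: pd.Series) -> pd.Series:
    """Vectorized :func:`map_code_to_heading` over a Series of code strings."""
    parsed = codes.str.strip().str.extract(_CODE_RE, expand=True)
    bad = parsed[0].isna()
    if bad.any():
        offenders = codes[bad].head(5).tolist()
        raise ValueError(
            f"{int(bad.sum())} unparseable ICD-10 code(s), e.g. {offenders}"
        )
    letters = parsed[0].str.upper()
    nums = parsed[1].astype(int)
    out = np.zeros(len(codes), dtype=np.int64)
    for letter, entries in _LETTER_TABLE.items():
        sel = letters == letter
        if not sel.any():
            continue
        n = nums[sel]
        res = np.zeros(int(sel.sum()), dtype=np.int64)
        for lo, hi, idx in entries:
            res[np.asarray((n >= lo) & (n <= hi))] = idx
        out[np.asarray(sel)] = res
    return pd.Series(out, index=codes.index)


def window_bounds(assessment_date: _dt.date, tau: int) -> tuple[_dt.date, _dt.date]:
    """Half-open look-back interval ``[assessment_date - len_tau, assessment_date)``.

    The assessment day itself is excluded, so a diagnosis coded on the day of
    the assessment never enters the features.
    """
    if tau not in WINDOW_DAYS:
        raise ValueError(f"tau must be in 1..5, got {tau!r}")
    if not isinstance(assessment_date, _dt.date):
        raise ValueError(f"assessment_date must be a date, got {assessment_date!r}")
    return assessment_date - _dt.timedelta(days=WINDOW_DAYS[tau]), assessment_date


@dataclass
class FrequencyMatrix:
    """Per-assessment code counts ``f_i(tau, ch)``.

    Attributes
    ----------
    values
        Integer array of shape ``(n_assessments, 5, 18)``; axis order is
        (assessment, window tau-1, heading ch-1).
    assessment_ids
        Aligned assessment identifiers.
    labels
        Optional aligned group labels (0 = control, 1 = risk).
    """

    values: np.ndarray
    assessment_ids: np.ndarray
    labels: np.ndarray | None = None
    patient_ids: np.ndarray | None = None
    clinical: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_WINDOWS, N_HEADINGS):
            raise ValueError(f"values must have shape (n, 5, 18), got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("frequency counts must be non-negative")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("frequency counts must be integers")

    @property
    def n_assessments(self) -> int:
        return self.values.shape[0]

    def no_history(self) -> np.ndarray:
        """Boolean (n, 5) flag: assessment has no physical-illness history in window tau."""
        return self.values.sum(axis=2) == 0

    def window(self, tau: int) -> np.ndarray:
        """The (n, 18) count slab for a single window."""
        if tau not in WINDOW_DAYS:
            raise ValueError(f"tau must be in 1..5, got {tau!r}")
        return self.values[:, tau - 1, :]


def frequency_matrix(assessments: pd.DataFrame, diagnoses: pd.DataFrame) -> FrequencyMatrix:
    """Count each patient's non-excluded diagnoses per heading per window.

    ``assessments`` needs columns ``assessment_id, patient_id,
    assessment_date``; ``diagnoses`` needs ``patient_id, diagnosis_date,
    icd10_code``.  Dates may be strings (ISO 8601) or datetimes.  A diagnosis
    on day d enters window tau of an assessment on day a iff
    ``1 <= (a - d).days <= WINDOW_DAYS[tau]`` (half-open convention).
    """
    a = assessments.reset_index(drop=True)
    a_dates = pd.to_datetime(a["assessment_date"], errors="coerce", format="ISO8601")
    if a_dates.isna().any():
        bad = a.loc[a_dates.isna(), "assessment_date"].head(5).tolist()
        raise ValueError(f"unparseable assessment_date value(s): {bad}")
    n = len(a)
    values = np.zeros((n, N_WINDOWS, N_HEADINGS), dtype=np.int64)

    if len(diagnoses):
        d = diagnoses.reset_index(drop=True)
        d_dates = pd.to_datetime(d["diagnosis_date"], errors="coerce", format="ISO8601")
        if d_dates.isna().any():
            bad_rows = d.loc[d_dates.isna()].head(5)
            raise ValueError(
                f"unparseable diagnosis_date in rows:\n{bad_rows.to_string()}"
            )
        heading = map_codes(d["icd10_code"].astype(str))
        d = pd.DataFrame(
            {"patient_id": d["patient_id"], "date": d_dates, "heading": heading}
        )
        d = d[d["heading"] != EXCLUDED]
        merged = pd.DataFrame(
            {"row": np.arange(n), "patient_id": a["patient_id"], "date": a_dates}
        ).merge(d, on="patient_id", how="inner", suffixes=("_a", "_d"))
        if len(merged):
            days = (merged["date_a"] - merged["date_d"]).dt.days.to_numpy()
            keep = (days >= 1) & (days <= WINDOW_DAYS[N_WINDOWS])
            merged = merged[keep]
            days = days[keep]
            # smallest window containing the event; windows are nested so the
            # event contributes to every tau >= level+1, realized as a
            # cumulative sum along the window axis below.
            level = np.searchsorted(
                [WINDOW_DAYS[t] for t in range(1, N_WINDOWS + 1)], days, side="left"
            )
            np.add.at(
                values,
                (merged["row"].to_numpy(), level, merged["heading"].to_numpy() - 1),
                1,
            )
            values = np.cumsum(values, axis=1)

    labels = a["outcome"].to_numpy() if "outcome" in a else None
    clinical = a["clinical_score"].to_numpy() if "clinical_score" in a else None
    return FrequencyMatrix(
        values=values,
        assessment_ids=a["assessment_id"].to_numpy(),
        labels=labels,
        patient_ids=a["patient_id"].to_numpy(),
        clinical=clinical,
    )


def concat_windows(F: FrequencyMatrix) -> np.ndarray:
    """Horizontally concatenate all five windows into a (n, 90) block.

    Column order is tau-major, heading-minor: columns 0..17 are window 1
    headings 1..18, columns 18..35 window 2, and so on.  The round trip
    ``concat_windows(F)[:, 18*(tau-1):18*tau] == F.window(tau)`` is exact.
    """
    if F.values.shape[1] != N_WINDOWS:
        raise ValueError("all five windows are required for concatenation")
    return F.values.reshape(F.n_assessments, N_WINDOWS * N_HEADINGS)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how the printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_labels(F: FrequencyMatrix, labels) -> np.ndarray:
    labels = np.asarray(F.labels if labels is None else labels)
    if labels.shape != (F.n_assessments,):
        raise ValueError(
            f"labels length {labels.shape} does not match {F.n_assessments} assessments"
        )
    return labels


def total_count_bin(total: np.ndarray) -> np.ndarray:
    """Bin total code counts into the six Table-1 categories (as string labels)."""
    edges = [1, 3, 6, 11, 21]
    idx = np.searchsorted(edges, np.asarray(total), side="right")
    return np.asarray(TOTAL_COUNT_BINS)[idx]


def tabulate_frequency_distribution(
    F: FrequencyMatrix, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Table-1 style report: assessments per total-code-count bin, per window, per group.

    Returns a tidy frame with columns ``window, group, bin, count, percent``;
    within every (window, group), counts sum to the group size and percents
    are round-half-up to 2 decimals of the group share.
    """
    labels = _check_labels(F, labels)
    rows = []
    for group, mask in (("control", labels == 0), ("risk", labels == 1)):
        gsize = int(mask.sum())
        if gsize == 0:
            logger.warning("group %r is empty; reporting zero counts", group)
        for tau in range(1, N_WINDOWS + 1):
            totals = F.window(tau)[mask].sum(axis=1)
            binned = total_count_bin(totals)
            for b in TOTAL_COUNT_BINS:
                cnt = int((binned == b).sum())
                pct = round_half_up(100.0 * cnt / gsize) if gsize else 0.0
                rows.append((tau, group, b, cnt, pct))
    return pd.DataFrame(rows, columns=["window", "group", "bin", "count", "percent"])


def tabulate_chapter_prevalence(
    F: FrequencyMatrix, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Table-2 style report: assessments with >= 1 code per heading/window/group.

    Prevalence counts presence, not frequency: an assessment with seven codes
    in a heading counts once.
    """
    labels = _check_labels(F, labels)
    rows = []
    for group, mask in (("control", labels == 0), ("risk", labels == 1)):
        gsize = int(mask.sum())
        if gsize == 0:
            logger.warning("group %r is empty; reporting zero counts", group)
        for tau in range(1, N_WINDOWS + 1):
            present = (F.window(tau)[mask] >= 1).sum(axis=0)
            for h in HEADINGS:
                cnt = int(present[h.index - 1])
                pct = round_half_up(100.0 * cnt / gsize) if gsize else 0.0
                rows.append((tau, group, h.index, h.roman, cnt, pct))
    return pd.DataFrame(
        rows, columns=["window", "group", "heading_index", "heading", "count", "percent"]
    )
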
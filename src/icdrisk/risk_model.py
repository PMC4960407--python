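"""Suicide-risk probability lookup table and assessment scoring.

Training assessments are labelled control (never attempted) or risk (>= 1
attempt within 90 days of an assessment).  For each look-back window tau,
chapter heading ch and frequency bin j, the lookup table PT holds the
empirical probability that an assessment whose heading count falls in that
bin belongs to the risk group.  Scoring a new assessment looks up pt for
each of its nonzero (tau, ch) cells, thresholds it with a Heaviside step at
theta, and sums the resulting indicators (optionally weighted by pt).

Zero counts never enter the histograms or the score: absence of history in a
heading is uninformative by construction, only presence at some intensity is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .chapters import N_HEADINGS, N_WINDOWS, FrequencyMatrix

logger = logging.getLogger(__name__)

#: Inclusive bounds of the five frequency bins, j = 1..5.  A count of zero
#: belongs to no bin.
BIN_BOUNDS: tuple[tuple[int, int | None], ...] = (
    (1, 2),
    (3, 5),
    (6, 10),
    (11, 20),
    (21, None),
)
BIN_LABELS = ("1-2", "3-5", "6-10", "11-20", ">20")
N_BINS = 5

_BIN_EDGES = np.array([1, 3, 6, 11, 21])

Variant = Literal["normalized-ratio", "raw-ratio"]
Mode = Literal["binary", "weighted"]

MODELS = ("tau1", "tau2", "tau3", "tau4", "tau5", "combined")


def bin_index(f: int) -> int:
    """Frequency bin j in 1..5 for a positive count; 0 (no bin) for f == 0.

    Bins are 1-2, 3-5, 6-10, 11-20, >20.
    """
    if isinstance(f, (bool, float)) and not float(f).is_integer():
        raise ValueError(f"count must be a non-negative integer, got {f!r}")
    f = int(f)
    if f < 0:
        raise ValueError(f"count must be non-negative, got {f}")
    if f == 0:
        return 0
    return int(np.searchsorted(_BIN_EDGES, f, side="right"))


def bin_indices(F: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bin_index`: 0 where F == 0, else j in 1..5."""
    F = np.asarray(F)
    if (F < 0).any():
        raise ValueError("counts must be non-negative")
    return np.searchsorted(_BIN_EDGES, F, side="right")


@dataclass
class GroupHistogram:
    """Bin-occupancy counts ``Hist_j(tau, ch)`` for one training group.

    ``counts[tau-1, ch-1, j-1]`` is the number of the group's assessments
    whose count f(tau, ch) falls in bin j.  Assessments with f == 0
    contribute nowhere, so for each (tau, ch) the bins sum to the number of
    group assessments with a nonzero count there.
    """

    counts: np.ndarray
    group: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_WINDOWS, N_HEADINGS, N_BINS):
            raise ValueError(f"histogram must be (5, 18, 5), got {self.counts.shape}")


def build_histograms(
    F_train: FrequencyMatrix, labels: np.ndarray | None = None
) -> tuple[GroupHistogram, GroupHistogram]:
    """Control and risk bin-occupancy histograms from training frequencies."""
    labels = np.asarray(F_train.labels if labels is None else labels)
    if labels.shape != (F_train.n_assessments,):
        raise ValueError("labels do not align with the frequency matrix")
    if not (labels == 0).any() or not (labels == 1).any():
        raise ValueError("training data must contain both control and risk assessments")

    binned = bin_indices(F_train.values)  # (n, 5, 18), values 0..5
    out = []
    for group, mask in (("control", labels == 0), ("risk", labels == 1)):
        sub = binned[mask]
        counts = np.stack(
            [(sub == j).sum(axis=0) for j in range(1, N_BINS + 1)], axis=-1
        ).astype(np.int64)
        out.append(GroupHistogram(counts=counts, group=group))
    return out[0], out[1]


@dataclass
class LookupTable:
    """Risk-probability lookup PT indexed by (tau, ch, j).

    ``probabilities[tau-1, ch-1, j-1]`` is pt in [0, 1], or NaN where the bin
    was empty in both training groups (undefined cell; scores treat it as a
    zero contribution).
    """

    probabilities: np.ndarray
    variant: Variant
    theta: float
    n_control: int
    n_risk: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (N_WINDOWS, N_HEADINGS, N_BINS):
            raise ValueError(
                f"lookup must be (5, 18, 5), got {self.probabilities.shape}"
            )
        defined = ~np.isnan(self.probabilities)
        if ((self.probabilities[defined] < 0) | (self.probabilities[defined] > 1)).any():
            raise ValueError("defined probabilities must lie in [0, 1]")

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.probabilities).sum())

    def lookup(self, tau: int, ch: int, j: int) -> float:
        """pt(tau, ch, j); NaN if the cell is undefined."""
        return float(self.probabilities[tau - 1, ch - 1, j - 1])

    def to_json(self) -> str:
        payload = {
            "dimensions": {"windows": N_WINDOWS, "headings": N_HEADINGS, "bins": N_BINS},
            "bin_bounds": [list(b) for b in BIN_BOUNDS],
            "variant": self.variant,
            "theta": self.theta,
            "n_control": self.n_control,
            "n_risk": self.n_risk,
            "probabilities": [
                [[None if np.isnan(p) else p for p in row] for row in slab]
                for slab in self.probabilities
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LookupTable":
        payload = json.loads(text)
        probs = np.array(
            [
                [[np.nan if p is None else p for p in row] for row in slab]
                for slab in payload["probabilities"]
            ],
            dtype=float,
        )
        return cls(
            probabilities=probs,
            variant=payload["variant"],
            theta=payload["theta"],
            n_control=payload["n_control"],
            n_risk=payload["n_risk"],
        )


def build_lookup(
    F_train: FrequencyMatrix,
    labels: np.ndarray | None = None,
    variant: Variant = "normalized-ratio",
    theta: float = 0.5,
) -> LookupTable:
    """Estimate the lookup table PT from labelled training frequencies.

    Under the default ``"normalized-ratio"`` variant each group's histogram
    row is first normalized to within-group bin proportions h_R, h_C (so the
    12%:88% class imbalance does not drown the risk signal) and
    pt = h_R / (h_R + h_C).  The ``"raw-ratio"`` variant uses raw counts,
    pt = n_R / (n_R + n_C).  Cells empty in both groups are NaN (undefined).
    """
    if variant not in ("normalized-ratio", "raw-ratio"):
        raise ValueError(f"unknown lookup variant {variant!r}")
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    control, risk = build_histograms(F_train, labels)
    c = control.counts.astype(float)
    r = risk.counts.astype(float)
    if variant == "normalized-ratio":
        c_tot = c.sum(axis=2, keepdims=True)
        r_tot = r.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(c_tot > 0, c / c_tot, 0.0)
            r = np.where(r_tot > 0, r / r_tot, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(c + r > 0, r / (c + r), np.nan)
    labels_arr = np.asarray(F_train.labels if labels is None else labels)
    table = LookupTable(
        probabilities=probs,
        variant=variant,
        theta=theta,
        n_control=int((labels_arr == 0).sum()),
        n_risk=int((labels_arr == 1).sum()),
    )
    if table.n_undefined:
        logger.info("lookup table has %d undefined cell(s)", table.n_undefined)
    return table


def heaviside(p: float, theta: float) -> int:
    """Threshold a lookup probability: 1 if p >= theta else 0.

    Ties at the threshold count as risk.  An undefined cell (NaN) contributes 0.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if p is None or np.isnan(p):
        return 0
    return int(p >= theta)


@dataclass
class RiskScore:
    """An assessment's algorithmic risk score with its per-cell trace.

    ``components`` maps (tau, ch) to the cell's contribution; the score is
    exactly their sum.
    """

    value: float
    model: str
    mode: Mode
    components: dict[tuple[int, int], float] = field(default_factory=dict)


def _model_windows(model: str | int) -> list[int]:
    if isinstance(model, (int, np.integer)):
        model = f"tau{int(model)}"
    if model == "combined":
        return list(range(1, N_WINDOWS + 1))
    if model in MODELS:
        return [int(model[3:])]
    raise ValueError(f"model must be one of {MODELS} or 1..5, got {model!r}")


def score_assessment(
    f_row: np.ndarray,
    table: LookupTable,
    model: str | int = "combined",
    mode: Mode = "binary",
) -> RiskScore:
    """RiskScore_Algorithm for one assessment from its (5, 18) frequency row.

    For every (tau, ch) in the model's index set with a nonzero count, the
    lookup probability at that count's bin is thresholded at the table's
    theta; ``binary`` mode sums the indicators, ``weighted`` mode sums
    pt * indicator.  Chapters with f == 0 and undefined cells contribute 0.
    """
    f_row = np.asarray(f_row)
    if f_row.shape != (N_WINDOWS, N_HEADINGS):
        raise ValueError(f"frequency row must be (5, 18), got {f_row.shape}")
    if mode not in ("binary", "weighted"):
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    windows = _model_windows(model)
    components: dict[tuple[int, int], float] = {}
    for tau in windows:
        for ch in range(1, N_HEADINGS + 1):
            j = bin_index(int(f_row[tau - 1, ch - 1]))
            if j == 0:
                continue
            pt = table.lookup(tau, ch, j)
            ind = heaviside(pt, table.theta)
            if ind:
                components[(tau, ch)] = pt * ind if mode == "weighted" else float(ind)
    model_name = f"tau{windows[0]}" if len(windows) == 1 else "combined"
    return RiskScore(
        value=float(sum(components.values())),
        model=model_name,
        mode=mode,
        components=components,
    )


def score_matrix(
    F: FrequencyMatrix | np.ndarray,
    table: LookupTable,
    model: str | int = "combined",
    mode: Mode = "binary",
) -> np.ndarray:
    """Vectorized scores for every assessment; matches :func:`score_assessment`."""
    values = F.values if isinstance(F, FrequencyMatrix) else np.asarray(F)
    windows = np.array(_model_windows(model)) - 1
    binned = bin_indices(values[:, windows, :])  # (n, w, 18), 0..5
    padded = np.concatenate(
        [np.full((N_WINDOWS, N_HEADINGS, 1), np.nan), table.probabilities], axis=2
    )  # j==0 slot -> NaN -> no contribution
    t_idx = windows[None, :, None]
    c_idx = np.arange(N_HEADINGS)[None, None, :]
    pts = padded[t_idx, c_idx, binned]
    fire = (~np.isnan(pts)) & (pts >= table.theta)
    contrib = np.where(fire, pts if mode == "weighted" else 1.0, 0.0)
    return contrib.sum(axis=(1, 2))
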
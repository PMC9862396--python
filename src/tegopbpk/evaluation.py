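"""PK parameters (NCA) and model-evaluation statistics.

The evaluation statistics mirror standard PBPK practice: the mean relative
deviation MRD = 10^sqrt(mean((log10 Cpred - log10 Cobs)^2)) summarises the
fit of a predicted concentration-time curve to one observed dataset; the
geometric mean fold error GMFE = 10^mean(|log10 PKpred - log10 PKobs|)
summarises predicted vs observed PK parameters; the two-fold fraction is
the percentage of predictions within [0.5, 2]x of the observation
(boundary inclusive).  Pairs with a non-positive member (LLOQ placeholders)
are excluded and counted.

AUCs use the linear-up/log-down trapezoid; the terminal slope lambda_z is
a log-linear regression over the tail window with the best adjusted R^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    """Raised when a metric has no valid pairs or a dataset is malformed."""


@dataclass(frozen=True)
class ObservedDataset:
    """One analyte's concentration-time records from one study arm."""

    study_id: str
    analyte: str  # "tegoprazan" | "M1"
    times: tuple[float, ...]  # h
    concentrations: tuple[float, ...]  # ng/mL
    regimen: dict = field(default_factory=dict)  # dose_mg, n_doses, interval_h, perpetrator...
    fed_state: str = "fasted"

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size != len(self.concentrations):
            raise EvaluationError(f"{self.study_id}: times and concentrations differ in length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
            raise EvaluationError(f"{self.study_id}: times must be nonnegative and sorted")
        if any(c < 0 for c in self.concentrations):
            raise EvaluationError(f"{self.study_id}: concentrations must be >= 0")

    @property
    def m(self) -> int:
        """Number of observed concentrations."""
        return len(self.times)


@dataclass(frozen=True)
class PKParameters:
    """Non-compartmental summary of one concentration-time profile."""

    auc_first: float  # ng*h/mL over the first dosing interval
    auc_ss: float  # ng*h/mL over the final dosing interval
    auc_inf: float | None  # ng*h/mL extrapolated; None if lambda_z inestimable
    cmax_first: float  # ng/mL
    cmax_ss: float  # ng/mL
    tmax: float  # h
    lambda_z: float | None  # 1/h
    auc_inf_flag: str | None = None  # reason when auc_inf is None


@dataclass(frozen=True)
class EvaluationReport:
    mrd_per_dataset: dict[str, float]
    gmfe_per_parameter: dict[str, float]
    twofold_percent: dict[str, float]  # per analyte
    n_parameters: int
    n_excluded_pairs: int = 0


def _positive_pairs(predicted, observed) -> tuple[np.ndarray, np.ndarray, int]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise EvaluationError("predicted and observed series must be paired")
    ok = (p > 0) & (o > 0)
    if not ok.any():
        raise EvaluationError("no valid (positive) predicted/observed pairs")
    return p[ok], o[ok], int((~ok).sum())


def mrd(predicted, observed) -> float:
    """Mean relative deviation, 10^RMS of log10 errors; >= 1 always."""
    p, o, _ = _positive_pairs(predicted, observed)
    x = np.mean((np.log10(p) - np.log10(o)) ** 2)
    return float(10.0 ** math.sqrt(x))


def gmfe(predicted_params, observed_params) -> float:
    """Geometric mean fold error, 10^mean(|log10 fold error|); >= 1 always."""
    p, o, _ = _positive_pairs(predicted_params, observed_params)
    x = np.mean(np.abs(np.log10(p) - np.log10(o)))
    return float(10.0**x)


def twofold_fraction(predicted, observed) -> float:
    """Percent of pairs whose ratio lies in [0.5, 2.0], boundary inclusive."""
    p, o, _ = _positive_pairs(predicted, observed)
    ratio = p / o
    return float(100.0 * np.mean((ratio >= 0.5) & (ratio <= 2.0)))


# ---------------------------------------------------------------------------
# Non-compartmental analysis
# ---------------------------------------------------------------------------

def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """Trapezoid AUC: linear while rising, log-linear while declining."""
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * 0.5 * (c0 + c1)
    return auc


def _window_auc(t: np.ndarray, c: np.ndarray, lo: float, hi: float) -> float:
    grid = np.unique(np.clip(np.concatenate([t, [lo, hi]]), lo, hi))
    cc = np.interp(grid, t, c)
    return _auc_lin_up_log_down(grid, cc)


def terminal_slope(t: np.ndarray, c: np.ndarray, min_points: int = 3, max_points: int = 8):
    """lambda_z (1/h) from the tail window with the best adjusted R^2.

    Only strictly positive concentrations after the peak are considered;
    returns (lambda_z, n_points) or (None, reason).
    """
    pos = c > 0
    if pos.sum() < min_points:
        return None, "fewer than 3 positive concentrations"
    i_max = int(np.argmax(c))
    tt, cc = t[i_max:][pos[i_max:]], c[i_max:][pos[i_max:]]
    if tt.size < min_points:
        return None, "fewer than 3 positive terminal points"
    best = None
    for k in range(min_points, min(max_points, tt.size) + 1):
        x, y = tt[-k:], np.log(cc[-k:])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        adj_r2 = 1.0 - (1.0 - (1.0 - ss_res / ss_tot)) * (k - 1) / (k - 2)
        if best is None or adj_r2 > best[0]:
            best = (adj_r2, -slope, k)
    if best is None:
        return None, "no declining log-linear tail"
    return best[1], best[2]


def compute_pk_parameters(
    times, concentrations, dosing_interval: float = 24.0, n_doses: int = 1
) -> PKParameters:
    """NCA of one profile: interval AUCs, Cmax/Tmax, lambda_z, AUC_inf."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 3:
        raise EvaluationError("need at least 3 points for NCA")
    auc_first = _window_auc(t, c, 0.0, dosing_interval)
    t_last_dose = (n_doses - 1) * dosing_interval
    auc_ss = _window_auc(t, c, t_last_dose, t_last_dose + dosing_interval)
    first = (t >= 0) & (t <= dosing_interval)
    ss = (t >= t_last_dose) & (t <= t_last_dose + dosing_interval)
    cmax_first = float(c[first].max()) if first.any() else float(c.max())
    cmax_ss = float(c[ss].max()) if ss.any() else float(c.max())
    tmax = float(t[np.argmax(c)])

    lam, info = terminal_slope(t, c)
    if lam is None:
        return PKParameters(auc_first, auc_ss, None, cmax_first, cmax_ss, tmax, None, info)
    c_last = c[c > 0][-1]
    t_full = _window_auc(t, c, 0.0, float(t[-1]))
    auc_inf = t_full + c_last / lam
    return PKParameters(auc_first, auc_ss, float(auc_inf), cmax_first, cmax_ss, tmax, float(lam))


def evaluate(pairs: list[tuple[ObservedDataset, np.ndarray]]) -> EvaluationReport:
    """Score model predictions against observed datasets.

    ``pairs`` holds (dataset, predicted concentrations at the dataset's
    observation times).  MRD per dataset; GMFE over AUC and Cmax across
    datasets; two-fold percentages pooled per analyte.
    """
    mrds: dict[str, float] = {}
    pooled: dict[str, tuple[list, list]] = {}
    auc_pred, auc_obs, cmax_pred, cmax_obs = [], [], [], []
    excluded = 0
    for ds, pred in pairs:
        pred = np.asarray(pred, dtype=float)
        key = f"{ds.study_id}:{ds.analyte}"
        mrds[key] = mrd(pred, ds.concentrations)
        _, _, n_bad = _positive_pairs(pred, ds.concentrations)
        excluded += n_bad
        p_list, o_list = pooled.setdefault(ds.analyte, ([], []))
        p_list.extend(pred)
        o_list.extend(ds.concentrations)
        interval = float(ds.regimen.get("interval_h", 24.0))
        n_doses = int(ds.regimen.get("n_doses", 1))
        if ds.m >= 3:
            obs_pk = compute_pk_parameters(ds.times, ds.concentrations, interval, n_doses)
            pred_pk = compute_pk_parameters(ds.times, pred, interval, n_doses)
            if obs_pk.auc_inf and pred_pk.auc_inf:
                auc_pred.append(pred_pk.auc_inf)
                auc_obs.append(obs_pk.auc_inf)
            cmax_pred.append(pred_pk.cmax_first)
            cmax_obs.append(obs_pk.cmax_first)
    gmfes = {}
    if auc_pred:
        gmfes["AUC_inf"] = gmfe(auc_pred, auc_obs)
    if cmax_pred:
        gmfes["Cmax"] = gmfe(cmax_pred, cmax_obs)
    twofold = {an: twofold_fraction(p, o) for an, (p, o) in pooled.items()}
    return EvaluationReport(
        mrd_per_dataset=mrds,
        gmfe_per_parameter=gmfes,
        twofold_percent=twofold,
        n_parameters=len(auc_pred) + len(cmax_pred),
        n_excluded_pairs=excluded,
    )


# ---------------------------------------------------------------------------
# Observed-data file format
# ---------------------------------------------------------------------------

_COLUMNS = ["study_id", "analyte", "time_h", "conc_ng_mL", "regimen", "fed"]


def write_datasets(datasets: list[ObservedDataset], path: str | Path) -> None:
    """Write datasets as delimited text (lossless round-trip)."""
    rows = []
    for ds in datasets:
        reg = json.dumps(ds.regimen, sort_keys=True)
        for t, c in zip(ds.times, ds.concentrations):
            rows.append((ds.study_id, ds.analyte, t, c, reg, ds.fed_state))
    # %.17g guarantees a lossless float round trip through the text format
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(
        path, index=False, na_rep="NA", float_format="%.17g"
    )


def read_datasets(path: str | Path) -> list[ObservedDataset]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise EvaluationError(f"{path}: missing columns {missing}")
    out = []
    for (sid, analyte, reg, fed), grp in frame.groupby(
        ["study_id", "analyte", "regimen", "fed"], sort=False
    ):
        out.append(
            ObservedDataset(
                study_id=str(sid),
                analyte=str(analyte),
                times=tuple(grp["time_h"].astype(float)),
                concentrations=tuple(grp["conc_ng_mL"].astype(float)),
                regimen=json.loads(reg),
                fed_state=str(fed),
            )
        )
    return out
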
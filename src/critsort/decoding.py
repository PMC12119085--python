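"""Per-timepoint linear decoding with leave-one-subject-out transfer.

A linear discriminant (pooled within-class covariance, analytic
shrinkage) is trained per subject and per timepoint on *all* trials,
irrespective of response or criterion condition.  Classifiers are then
applied to every other subject; per-test-subject performance is the
average of the contributing classifiers' AUC time series, so for N
subjects N*(N-1) classifier/test pairs are evaluated.

Post-hoc sorting assigns target trials to response cells; within a cell,
AUC contrasts the sorted target trials against the condition's no-target
trials.  By default the no-target reference pools all responses of the
condition (``reference='pooled_noise'``): response-sorting both classes
(``reference='within_cell'``) is also available but provably reverses
the criterion effect in the seen cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

from .synth import OCCIPITOPARIETAL, SubjectDataset

__all__ = [
    "TimepointClassifier",
    "DecodingResult",
    "ActivationPattern",
    "ContrastResult",
    "train_timepoint_classifiers",
    "auc_score",
    "loso_cv",
    "balance_trials",
    "posthoc_cells",
    "find_peaks",
    "forward_transform",
    "criterion_contrast",
    "CHANNEL_SETS",
]

CHANNEL_SETS: Mapping[str, tuple[str, ...]] = {"occipitoparietal": OCCIPITOPARIETAL}

CLASS_ORDER = ("no_target", "target")  # decision values increase toward target


@dataclass
class TimepointClassifier:
    """One linear discriminant per timepoint, shared channel space."""

    weights: np.ndarray  # (n_channels, n_times)
    intercept: np.ndarray  # (n_times,)
    training_subject: int
    channel_names: tuple[str, ...]
    class_order: tuple[str, str] = CLASS_ORDER
    zscore_mean: np.ndarray | None = None  # (n_channels, n_times)
    zscore_sd: np.ndarray | None = None
    shrinkage_used: np.ndarray | None = None  # per-timepoint gamma

    def decision_values(self, epochs: np.ndarray) -> np.ndarray:
        """Per-trial, per-timepoint discriminant scores for (n, C, T) data."""
        x = epochs
        if self.zscore_mean is not None:
            x = (x - self.zscore_mean[None]) / self.zscore_sd[None]
        return np.einsum("nct,ct->nt", x, self.weights, optimize=True) + self.intercept


@dataclass
class ActivationPattern:
    """Haufe-style forward-transformed weights (unit-normalised)."""

    pattern: np.ndarray  # (n_channels, n_times)
    times: np.ndarray
    channel_names: tuple[str, ...]


def _resolve_channels(
    ds: SubjectDataset, channel_subset: str | Sequence[str] | None
) -> np.ndarray:
    if channel_subset is None or channel_subset == "all":
        return np.arange(len(ds.channel_names))
    if isinstance(channel_subset, str):
        try:
            names = CHANNEL_SETS[channel_subset]
        except KeyError:
            raise ValueError(
                f"unknown channel set {channel_subset!r}; "
                f"available: {sorted(CHANNEL_SETS)} or 'all'"
            ) from None
    else:
        names = tuple(channel_subset)
    lookup = {name: i for i, name in enumerate(ds.channel_names)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise ValueError(f"channels not in dataset montage: {missing}")
    return np.array([lookup[n] for n in names])


def _ledoit_wolf_gamma(z: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Analytic shrinkage intensity per timepoint.

    ``z`` is class-centred data (n, C, T); ``cov`` the pooled covariance
    (T, C, C).  Returns gamma in [0, 1] per timepoint.
    """
    n, c, _ = z.shape
    mu = np.trace(cov, axis1=1, axis2=2) / c
    eye = np.eye(c)
    dist2 = np.sum((cov - mu[:, None, None] * eye) ** 2, axis=(1, 2))
    sq_norms = np.sum(z**2, axis=1)  # (n, T): ||z_i||^2 per timepoint
    cov_norm2 = np.sum(cov**2, axis=(1, 2))
    b2 = (np.sum(sq_norms**2, axis=0) / n**2) - cov_norm2 / n
    b2 = np.clip(b2, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(dist2 > 0, np.minimum(1.0, b2 / dist2), 1.0)
    return gamma


def train_timepoint_classifiers(
    ds: SubjectDataset,
    channel_subset: str | Sequence[str] | None = None,
    shrinkage: float | Literal["ledoit"] | None = "ledoit",
    zscore: bool = True,
    time_indices: Sequence[int] | None = None,
) -> TimepointClassifier:
    """Train one LDA per timepoint on all of a subject's trials.

    Training ignores responses and criterion conditions.  The pooled
    within-class covariance is conditioned by shrinkage toward the
    identity-scaled covariance: ``'ledoit'`` picks the analytic
    Ledoit-Wolf intensity per timepoint, a float fixes it, ``None``
    disables it (and singular covariance then raises with advice).
    Equal class priors are used; the intercept places the boundary
    midway between class means.
    """
    ch = _resolve_channels(ds, channel_subset)
    x = ds.epochs[:, ch, :].astype(float)
    if time_indices is not None:
        x = x[:, :, np.asarray(time_indices)]
    y = ds.is_target
    n0, n1 = int((~y).sum()), int(y.sum())
    if min(n0, n1) < 2:
        raise ValueError(f"need >=2 trials per class, got {n0} / {n1}")

    mean = sd = None
    if zscore:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mean[None]) / sd[None]

    mu0 = x[~y].mean(axis=0)  # (C, T)
    mu1 = x[y].mean(axis=0)
    z = x.copy()
    z[~y] -= mu0[None]
    z[y] -= mu1[None]
    n = x.shape[0]
    cov = np.einsum("nct,ndt->tcd", z, z, optimize=True) / (n - 2)

    n_times = x.shape[2]
    c = ch.size
    eye = np.eye(c)
    if shrinkage is None:
        gamma = np.zeros(n_times)
    elif shrinkage == "ledoit":
        gamma = _ledoit_wolf_gamma(z, cov)
    else:
        g = float(shrinkage)
        if not 0.0 <= g <= 1.0:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        gamma = np.full(n_times, g)
    mu_tr = np.trace(cov, axis1=1, axis2=2) / c
    cov_sh = (1 - gamma)[:, None, None] * cov + (gamma * mu_tr)[:, None, None] * eye

    delta = (mu1 - mu0).T  # (T, C)
    try:
        w = np.linalg.solve(cov_sh, delta[..., None])[..., 0]  # (T, C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; pass shrinkage='ledoit' or a "
            "positive shrinkage intensity"
        ) from err
    weights = w.T  # (C, T)
    midpoint = (mu0 + mu1) / 2.0
    intercept = -np.einsum("ct,ct->t", weights, midpoint)

    return TimepointClassifier(
        weights=weights,
        intercept=intercept,
        training_subject=ds.subject_id,
        channel_names=tuple(ds.channel_names[i] for i in ch),
        zscore_mean=mean,
        zscore_sd=sd,
        shrinkage_used=gamma,
    )


def _auc_over_time(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-based (Mann-Whitney) AUC per column; ties count 1/2."""
    ranks = _stats.rankdata(values, axis=0, method="average")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    r1 = ranks[labels].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_score(decision_values: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC of ``decision_values`` for binary ``labels``.

    Ties contribute 1/2.  Raises if only one class is present — which is
    exactly what an empty post-hoc cell produces downstream.
    """
    v = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("decision_values and labels must be 1-D and equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute AUC")
    return float(_auc_over_time(v[:, None], y)[0])


def posthoc_cells(
    ds: SubjectDataset, mode: Literal["yes_no", "pas"] | None = None
) -> pd.DataFrame:
    """Per-trial (condition, visibility) assignment from the responses.

    Yes/no: a press (response 1) is 'seen', no press 'unseen'.  PAS:
    level 0 is 'unseen', levels 1-3 'seen'; the raw level is kept in
    ``pas_level``.  Every trial maps to exactly one cell.
    """
    mode = mode or ds.mode
    resp = ds.response
    if mode == "yes_no":
        if not np.isin(resp, [0, 1]).all():
            raise ValueError("yes_no mode requires responses in {0, 1}")
    elif mode == "pas":
        if not np.isin(resp, [0, 1, 2, 3]).all():
            raise ValueError("pas mode requires responses in {0, 1, 2, 3}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(
        {
            "condition": ds.condition,
            "visibility": np.where(resp > 0, "seen", "unseen"),
        }
    )
    if mode == "pas":
        out["pas_level"] = resp
    return out


def balance_trials(
    ds: SubjectDataset, seed: int | None = 0, mode: str | None = None
) -> np.ndarray:
    """Equate per stimulus-response-cell counts across criterion conditions.

    For every (stimulus class, response level) cell, the liberal and
    conservative conditions keep ``min`` of the two counts, selected
    uniformly without replacement under ``seed``.  Response level means
    the raw response: seen/unseen for yes-no data, each PAS level for
    PAS data.  Zero-count cells stay zero.  Returns sorted trial
    indices.
    """
    rng = np.random.default_rng(seed)
    conds = np.unique(ds.condition)
    if set(conds) != {"liberal", "conservative"}:
        raise ValueError("both criterion conditions must be present")
    keep: list[np.ndarray] = []
    for stim in np.unique(ds.stimulus):
        for level in np.unique(ds.response):
            in_cell = (ds.stimulus == stim) & (ds.response == level)
            lib = np.flatnonzero(in_cell & (ds.condition == "liberal"))
            cons = np.flatnonzero(in_cell & (ds.condition == "conservative"))
            m = min(lib.size, cons.size)
            if m == 0:
                continue
            for idx in (lib, cons):
                if idx.size > m:
                    idx = rng.choice(idx, size=m, replace=False)
                keep.append(idx)
    if not keep:
        raise ValueError("balancing removed every trial")
    out = np.concatenate(keep)
    out.sort()
    return out


def _cell_indices(
    ds: SubjectDataset,
    scheme: str,
    idx: np.ndarray,
    reference: str,
) -> dict[str, np.ndarray]:
    """Map cell name -> trial indices (into the full dataset)."""
    cond = ds.condition[idx]
    target = ds.is_target[idx]
    resp = ds.response[idx]
    if scheme == "all":
        return {"all": idx}
    cells: dict[str, np.ndarray] = {}
    if scheme == "condition":
        for c in ("liberal", "conservative"):
            cells[f"{c}:all"] = idx[cond == c]
        return cells
    if scheme == "condition_visibility":
        groups = [("seen", resp > 0), ("unseen", resp == 0)]
    elif scheme == "condition_pas":
        groups = [(f"pas{k}", resp == k) for k in range(4)]
    else:
        raise ValueError(f"unknown cell scheme {scheme!r}")
    for c in ("liberal", "conservative"):
        in_cond = cond == c
        for name, in_group in groups:
            targets = idx[in_cond & target & in_group]
            if reference == "pooled_noise":
                noises = idx[in_cond & ~target]
            elif reference == "within_cell":
                noises = idx[in_cond & ~target & in_group]
            else:
                raise ValueError(f"unknown reference {reference!r}")
            cells[f"{c}:{name}"] = np.concatenate([targets, noises])
    return cells


@dataclass
class DecodingResult:
    """Subject x cell x timepoint AUC with bookkeeping.

    Missing cells (one class absent after sorting) are NaN in ``auc``
    and flagged in ``n_trials``; they are never imputed.
    """

    auc: np.ndarray  # (n_subjects, n_cells, n_times)
    cells: tuple[str, ...]
    times: np.ndarray
    subjects: tuple[int, ...]
    n_trials: pd.DataFrame  # subject, cell, n_target, n_no_target
    provenance: dict

    def cell_index(self, cell: str) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            raise KeyError(f"no cell {cell!r}; available: {self.cells}") from None

    def grand_mean(self, cell: str = "all") -> np.ndarray:
        """Across-subject mean AUC time series for one cell."""
        return np.nanmean(self.auc[:, self.cell_index(cell), :], axis=0)

    def subject_series(self, cell: str) -> np.ndarray:
        return self.auc[:, self.cell_index(cell), :]

    def time_index(self, latency_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - latency_ms)))

    def summary_table(self, latencies: Sequence[float]) -> pd.DataFrame:
        """Per-cell grand-mean AUC at selected latencies (nearest sample)."""
        rows = []
        for lat in latencies:
            ti = self.time_index(lat)
            for cell in self.cells:
                rows.append(
                    {
                        "latency_ms": float(self.times[ti]),
                        "requested_ms": float(lat),
                        "cell": cell,
                        "mean_auc": float(
                            np.nanmean(self.auc[:, self.cell_index(cell), ti])
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def save_hdf5(self, path) -> None:
        import json

        with h5py.File(path, "w") as f:
            grp = f.create_group("results")
            grp.create_dataset("auc", data=self.auc)
            grp.create_dataset("times", data=self.times)
            grp.create_dataset("subjects", data=np.asarray(self.subjects))
            str_dt = h5py.string_dtype()
            grp.create_dataset("cells", data=list(self.cells), dtype=str_dt)
            grp.attrs["provenance_json"] = json.dumps(self.provenance)
            rec = self.n_trials.to_records(index=False)
            grp.create_dataset(
                "n_trials_csv",
                data=self.n_trials.to_csv(index=False),
                dtype=str_dt,
            )
            del rec


def loso_cv(
    cohort: Sequence[SubjectDataset],
    channel_subset: str | Sequence[str] | None = None,
    cell_scheme: Literal[
        "all", "condition", "condition_visibility", "condition_pas"
    ] = "all",
    balance_seed: int | None = None,
    reference: Literal["pooled_noise", "within_cell"] = "pooled_noise",
    shrinkage: float | Literal["ledoit"] | None = "ledoit",
    zscore: bool = True,
    time_indices: Sequence[int] | None = None,
    classifiers: Sequence[TimepointClassifier] | None = None,
) -> DecodingResult:
    """Leave-one-subject-out cross-validated per-timepoint decoding.

    Every subject's classifiers test every other subject; the AUC time
    series landing on the same test subject are averaged (average of
    AUCs, not of decision values), giving one series per subject and
    cell.  ``balance_seed`` activates per stimulus-response-cell trial
    balancing between the criterion conditions before testing.

    For sorted schemes each cell contrasts response-sorted target trials
    against the condition's no-target trials (see module docstring for
    the ``reference`` choice).

    ``time_indices`` restricts training and testing to a subset of
    samples (e.g. pre-identified peak latencies); ``classifiers`` reuses
    an already-trained set (one per subject, same order as the cohort,
    trained with the same ``time_indices``).
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    names = cohort[0].channel_names
    for ds in cohort[1:]:
        if ds.channel_names != names:
            raise ValueError(
                f"channel montage mismatch between subjects "
                f"{cohort[0].subject_id} and {ds.subject_id}"
            )
    if classifiers is None:
        classifiers = [
            train_timepoint_classifiers(
                ds, channel_subset, shrinkage, zscore, time_indices
            )
            for ds in cohort
        ]
    elif len(classifiers) != len(cohort):
        raise ValueError("need exactly one classifier set per subject")
    ch0 = _resolve_channels(cohort[0], channel_subset)
    times = cohort[0].times.copy()
    if time_indices is not None:
        times = times[np.asarray(time_indices)]
    n_times = times.size

    # fixed cell layout across subjects
    if cell_scheme == "all":
        cell_names: tuple[str, ...] = ("all",)
    elif cell_scheme == "condition":
        cell_names = ("liberal:all", "conservative:all")
    elif cell_scheme == "condition_visibility":
        cell_names = tuple(
            f"{c}:{v}"
            for c in ("liberal", "conservative")
            for v in ("seen", "unseen")
        )
    elif cell_scheme == "condition_pas":
        cell_names = tuple(
            f"{c}:pas{k}" for c in ("liberal", "conservative") for k in range(4)
        )
    else:
        raise ValueError(f"unknown cell scheme {cell_scheme!r}")

    auc = np.full((len(cohort), len(cell_names), n_times), np.nan)
    count_rows = []
    for si, ds in enumerate(cohort):
        idx = np.arange(ds.n_trials)
        if balance_seed is not None:
            idx = balance_trials(ds, seed=balance_seed + ds.subject_id)
        cells = _cell_indices(ds, cell_scheme, idx, reference)
        x = ds.epochs[:, ch0, :].astype(float)
        if time_indices is not None:
            x = x[:, :, np.asarray(time_indices)]
        dvs = [
            clf.decision_values(x)
            for ti, clf in enumerate(classifiers)
            if ti != si
        ]
        for ci, cell in enumerate(cell_names):
            cidx = cells.get(cell, np.array([], dtype=int))
            y = ds.is_target[cidx]
            n1, n0 = int(y.sum()), int((~y).sum())
            count_rows.append(
                {
                    "subject": ds.subject_id,
                    "cell": cell,
                    "n_target": n1,
                    "n_no_target": n0,
                }
            )
            if n1 == 0 or n0 == 0:
                warnings.warn(
                    f"subject {ds.subject_id}, cell {cell!r}: missing class "
                    f"(n_target={n1}, n_no_target={n0}); AUC flagged NaN",
                    stacklevel=2,
                )
                continue
            series = np.stack([_auc_over_time(dv[cidx], y) for dv in dvs])
            auc[si, ci] = series.mean(axis=0)

    provenance = {
        "cell_scheme": cell_scheme,
        "reference": reference,
        "balance_seed": balance_seed,
        "shrinkage": str(shrinkage),
        "zscore": zscore,
        "channel_subset": (
            channel_subset if isinstance(channel_subset, str) or channel_subset is None
            else list(channel_subset)
        ),
        "n_classifier_test_pairs": len(cohort) * (len(cohort) - 1),
    }
    return DecodingResult(
        auc=auc,
        cells=cell_names,
        times=times,
        subjects=tuple(ds.subject_id for ds in cohort),
        n_trials=pd.DataFrame(count_rows),
        provenance=provenance,
    )


def find_peaks(
    times: np.ndarray, series: np.ndarray, n_peaks: int = 3
) -> np.ndarray:
    """Latencies (ms) of the most prominent strict local maxima at t > 0.

    Edge samples never count as peaks.  Peaks are ranked by prominence
    (earlier latency wins ties) and returned sorted by latency; if fewer
    than ``n_peaks`` exist, the available ones are returned with a
    warning.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times.shape != series.shape or times.ndim != 1:
        raise ValueError("times and series must be 1-D and equal length")
    if times.max() <= 0:
        raise ValueError("series must cover a post-stimulus window")
    loc, _ = _sig.find_peaks(series)
    loc = loc[(times[loc] > 0) & (loc > 0) & (loc < times.size - 1)]
    if loc.size == 0:
        warnings.warn("no post-stimulus local maxima found", stacklevel=2)
        return np.array([])
    prom = _sig.peak_prominences(series, loc)[0]
    order = np.lexsort((times[loc], -prom))  # prominence desc, earlier first
    chosen = loc[order[:n_peaks]]
    if chosen.size < n_peaks:
        warnings.warn(
            f"only {chosen.size} local maxima found, {n_peaks} requested",
            stacklevel=2,
        )
    return np.sort(times[chosen])


def forward_transform(
    clf: TimepointClassifier, epochs: np.ndarray, normalize: bool = True
) -> ActivationPattern:
    """Activation pattern ``Sigma_X @ w`` per timepoint.

    ``epochs`` must be the training subject's (n, C, T) array in the
    classifier's channel space; the classifier's z-scoring is applied
    before computing the data covariance.  Normalisation to unit norm is
    presentation-only and can be disabled.
    """
    x = epochs.astype(float)
    if x.shape[1] != clf.weights.shape[0]:
        raise ValueError("epoch channel dimension does not match classifier")
    if clf.zscore_mean is not None:
        x = (x - clf.zscore_mean[None]) / clf.zscore_sd[None]
    xc = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("nct,ndt->tcd", xc, xc, optimize=True) / (x.shape[0] - 1)
    pattern = np.einsum("tcd,dt->ct", cov, clf.weights, optimize=True)
    if normalize:
        norms = np.linalg.norm(pattern, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        pattern = pattern / norms
    times = np.arange(pattern.shape[1], dtype=float)
    return ActivationPattern(pattern, times, clf.channel_names)


def _one_sided_t(diffs: np.ndarray) -> tuple[float, float]:
    """Paired one-sided t (greater than zero); degenerate cases handled."""
    n = diffs.size
    m = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 0.5
        return (np.inf, 0.0) if m > 0 else (-np.inf, 1.0)
    t = m / (sd / np.sqrt(n))
    p = float(_stats.t.sf(t, df=n - 1))
    return float(t), p


@dataclass
class ContrastResult:
    """Per-cell conservative-minus-liberal contrasts at chosen latencies."""

    table: pd.DataFrame
    deltas: dict[tuple[float, str], np.ndarray]


def criterion_contrast(
    result: DecodingResult, latencies: Sequence[float]
) -> ContrastResult:
    """Conservative-minus-liberal AUC differences with one-sided t-tests.

    For every requested latency (nearest sample) and every visibility
    level present in the result (plus a 'collapsed' average across
    levels), returns per-subject differences, their mean, and the
    one-sided paired t statistic and p value for conservative > liberal.
    No correction beyond restricting to the given latencies is applied.
    """
    levels = sorted(
        {
            cell.split(":", 1)[1]
            for cell in result.cells
            if cell.startswith("liberal:")
        }
    )
    if not levels:
        raise ValueError("result has no liberal/conservative cells to contrast")
    rows = []
    deltas: dict[tuple[float, str], np.ndarray] = {}
    for lat in latencies:
        ti = result.time_index(lat)
        level_deltas = []
        for level in levels:
            cons = result.auc[:, result.cell_index(f"conservative:{level}"), ti]
            lib = result.auc[:, result.cell_index(f"liberal:{level}"), ti]
            d = cons - lib
            level_deltas.append(d)
            dd = d[np.isfinite(d)]
            t, p = _one_sided_t(dd) if dd.size else (np.nan, np.nan)
            rows.append(
                {
                    "latency_ms": float(result.times[ti]),
                    "cell": level,
                    "n": dd.size,
                    "mean_delta": float(dd.mean()) if dd.size else np.nan,
                    "t": t,
                    "p_one_sided": p,
                }
            )
            deltas[(float(result.times[ti]), level)] = d
        if len(level_deltas) > 1:
            d = np.nanmean(np.stack(level_deltas), axis=0)
            dd = d[np.isfinite(d)]
            t, p = _one_sided_t(dd) if dd.size else (np.nan, np.nan)
            rows.append(
                {
                    "latency_ms": float(result.times[ti]),
                    "cell": "collapsed",
                    "n": dd.size,
                    "mean_delta": float(dd.mean()) if dd.size else np.nan,
                    "t": t,
                    "p_one_sided": p,
                }
            )
            deltas[(float(result.times[ti]), "collapsed")] = d
    return ContrastResult(pd.DataFrame(rows), deltas)
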
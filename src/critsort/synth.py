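"""Synthetic epoched-EEG cohort generator.

Each trial owns a latent SDT signal strength; multichannel epochs are a
linear forward model of that strength (per-component spatial patterns
times Gaussian temporal kernels) plus spatially correlated noise, and
the behavioural response is the criterion binning of the same latent
strength.  This makes the generator the ground-truth test bed for the
decoding pipeline: components with ``coupling=0`` carry class
information but no response dependence, components with ``coupling=1``
inherit the full criterion confound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "critsort-dataset-1"

# occipitoparietal montage of the source recordings; used as default
# channel names when n_channels matches.
OCCIPITOPARIETAL = (
    "Iz", "O1", "O2", "Oz", "P1", "P10", "P2", "P3", "P4", "P5", "P6",
    "P7", "P8", "P9", "PO10", "PO3", "PO4", "PO7", "PO8", "PO9", "POz", "Pz",
)

__all__ = [
    "GeneratorConfig",
    "SubjectDataset",
    "generate_trials",
    "generate_subject",
    "generate_cohort",
    "behavioral_table",
    "write_dataset",
    "read_dataset",
    "OCCIPITOPARIETAL",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generative parameters.

    ``n_trials`` is per criterion condition.  ``coupling[k]`` is the
    fraction of component-k amplitude driven by the trial's latent
    strength (the remainder is the deterministic class mean), so
    ``coupling=0`` yields class information without any criterion
    confound and ``coupling=1`` ties the component fully to the
    response-generating signal.
    """

    n_subjects: int = 12
    n_trials: int = 500
    p_target: float = 0.75
    n_channels: int = 22
    sample_rate: float = 256.0
    epoch_window: tuple[float, float] = (-100.0, 750.0)
    component_latencies: tuple[float, ...] = (137.0, 266.0, 430.0)
    component_widths: tuple[float, ...] = (25.0, 35.0, 45.0)
    coupling: tuple[float, ...] = (0.0, 1.0, 1.0)
    d_prime: float = 2.0
    liberal_criteria: tuple[float, ...] = (0.4,)
    conservative_criteria: tuple[float, ...] = (1.6,)
    mode: Literal["yes_no", "pas"] = "yes_no"
    condition_scheme: Literal["blockwise", "sessionwise"] = "blockwise"
    n_blocks: int = 10
    noise_sd: float = 1.0
    ar_coef: float = 0.0
    spatial_jitter: float = 0.15
    spatial_pattern_seed: int = 0
    trial_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_target < 1.0:
            raise ValueError("p_target must lie strictly between 0 and 1")
        t0, t1 = self.epoch_window
        for lat in self.component_latencies:
            if not t0 < lat < t1:
                raise ValueError(f"component latency {lat} outside epoch window")
        if not (
            len(self.component_latencies)
            == len(self.component_widths)
            == len(self.coupling)
        ):
            raise ValueError("latencies, widths and coupling must have equal length")
        if any(not 0.0 <= c <= 1.0 for c in self.coupling):
            raise ValueError("coupling entries must lie in [0, 1]")
        n_crit = 3 if self.mode == "pas" else 1
        for name in ("liberal_criteria", "conservative_criteria"):
            crit = getattr(self, name)
            if len(crit) != n_crit:
                raise ValueError(
                    f"{name} needs {n_crit} thresholds in {self.mode!r} mode"
                )
            if any(b <= a for a, b in zip(crit, crit[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms; includes 0 (stimulus onset) exactly."""
        step = 1000.0 / self.sample_rate
        n_pre = int(round(-self.epoch_window[0] / step))
        n_post = int(round(self.epoch_window[1] / step))
        return (np.arange(n_pre + n_post + 1) - n_pre) * step

    @property
    def criteria(self) -> dict[str, tuple[float, ...]]:
        return {
            "liberal": self.liberal_criteria,
            "conservative": self.conservative_criteria,
        }

    def expected_behavioral_c(self, condition: str) -> float:
        """Behavioural criterion c implied by the first axis threshold."""
        return self.criteria[condition][0] - self.d_prime / 2.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        obj = json.loads(text)
        for key in (
            "epoch_window",
            "component_latencies",
            "component_widths",
            "coupling",
            "liberal_criteria",
            "conservative_criteria",
        ):
            obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class SubjectDataset:
    """Epoched trials plus per-trial metadata for one subject."""

    subject_id: int
    epochs: np.ndarray  # (n_trials, n_channels, n_times)
    times: np.ndarray  # ms
    channel_names: tuple[str, ...]
    stimulus: np.ndarray  # {"target", "no_target"}
    condition: np.ndarray  # {"liberal", "conservative"}
    response: np.ndarray  # int, 0/1 (yes_no) or 0..3 (pas)
    latent_strength: np.ndarray
    session: np.ndarray
    block: np.ndarray
    mode: str
    config_json: str = ""

    def __post_init__(self) -> None:
        n, c, t = self.epochs.shape
        if self.times.size != t:
            raise ValueError("times length does not match epochs")
        if len(self.channel_names) != c:
            raise ValueError("channel_names length does not match epochs")
        for name in ("stimulus", "condition", "response", "latent_strength",
                     "session", "block"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match epochs")
        if not np.any(self.times == 0.0):
            raise ValueError("times must include 0 (stimulus onset)")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def is_target(self) -> np.ndarray:
        return self.stimulus == "target"


def _cohort_structure(config: GeneratorConfig):
    """Shared spatial patterns and noise mixing, fixed per cohort."""
    rng = np.random.default_rng(config.spatial_pattern_seed)
    n_comp = len(config.component_latencies)
    patterns = rng.normal(size=(n_comp, config.n_channels))
    patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    a = rng.normal(size=(config.n_channels, config.n_channels))
    cov = a @ a.T / config.n_channels + 0.5 * np.eye(config.n_channels)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)  # unit-diagonal spatial correlation
    chol = np.linalg.cholesky(corr)
    return patterns, chol


def _kernels(config: GeneratorConfig) -> np.ndarray:
    times = config.times
    lat = np.asarray(config.component_latencies)[:, None]
    wid = np.asarray(config.component_widths)[:, None]
    return np.exp(-0.5 * ((times[None, :] - lat) / wid) ** 2)


def _channel_names(config: GeneratorConfig) -> tuple[str, ...]:
    if config.n_channels == len(OCCIPITOPARIETAL):
        return OCCIPITOPARIETAL
    return tuple(f"ch{i:02d}" for i in range(config.n_channels))


def generate_trials(
    config: GeneratorConfig, subject_id: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw trial metadata (no epochs) for one subject.

    Returns the canonical trial table (subject, session, block,
    condition, stimulus, response, rt) and the latent strengths.  Used
    by :func:`generate_subject` and directly wherever behavioural-only
    cohorts suffice.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((config.trial_seed, int(subject_id)))
    )
    n_per_cond = config.n_trials
    n = 2 * n_per_cond

    if config.condition_scheme == "sessionwise":
        # one condition per session; order fixed lib-first (counter-
        # balancing is irrelevant for a synthetic cohort)
        condition = np.repeat(["liberal", "conservative"], n_per_cond)
        session = np.repeat([1, 2], n_per_cond)
        block = np.concatenate(
            [
                1 + (np.arange(n_per_cond) * config.n_blocks) // n_per_cond
                for _ in range(2)
            ]
        )
    else:
        # alternating blocks within a single session; both conditions get
        # exactly n_per_cond trials regardless of divisibility
        half = max(1, config.n_blocks // 2)
        base, rem = divmod(n_per_cond, half)
        sizes = [base + 1] * rem + [base] * (half - rem)
        block_list, cond_list = [], []
        for b in range(half):
            for j, cond_name in enumerate(("liberal", "conservative")):
                block_id = 2 * b + 1 + j
                block_list.append(np.full(sizes[b], block_id))
                cond_list.append(np.full(sizes[b], cond_name))
        block = np.concatenate(block_list)
        condition = np.concatenate(cond_list)
        session = np.ones(n, dtype=int)

    is_target = rng.random(n) < config.p_target
    latent = np.where(
        is_target,
        rng.normal(config.d_prime, 1.0, n),
        rng.normal(0.0, 1.0, n),
    )
    response = np.empty(n, dtype=int)
    for cond, crit in config.criteria.items():
        sel = condition == cond
        response[sel] = np.searchsorted(np.asarray(crit), latent[sel], side="left")

    table = pd.DataFrame(
        {
            "subject": int(subject_id),
            "session": session,
            "block": block,
            "condition": condition,
            "stimulus": np.where(is_target, "target", "no_target"),
            "response": response,
            "rt": np.nan,  # reaction times are out of scope
        }
    )
    return table, latent


def generate_subject(config: GeneratorConfig, subject_id: int) -> SubjectDataset:
    """Generate one subject's epoched dataset.

    Epochs follow ``sum_k pattern_k (x) kernel_k(t) * a_k(s)`` plus
    spatially correlated Gaussian noise, with
    ``a_k(s) = coupling_k * s + (1 - coupling_k) * class_mean``.
    Subject-specific patterns are the cohort patterns plus seeded
    jitter, so cross-subject decoding transfers.  Fixed seeds give
    bit-identical output.
    """
    table, latent = generate_trials(config, subject_id)
    n = len(table)
    patterns, chol = _cohort_structure(config)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.trial_seed, int(subject_id), 1))
    )
    subj_patterns = patterns + config.spatial_jitter * rng.normal(
        size=patterns.shape
    )
    subj_patterns /= np.linalg.norm(subj_patterns, axis=1, keepdims=True)

    kernels = _kernels(config)  # (n_comp, n_times)
    n_times = kernels.shape[1]
    class_mean = np.where(table["stimulus"].to_numpy() == "target", config.d_prime, 0.0)
    coupling = np.asarray(config.coupling)
    # (n_trials, n_comp) component amplitudes
    amps = coupling[None, :] * latent[:, None] + (1 - coupling)[None, :] * class_mean[:, None]
    signal = np.einsum("nk,kc,kt->nct", amps, subj_patterns, kernels, optimize=True)

    noise = rng.standard_normal((n, n_times, config.n_channels))
    if config.ar_coef > 0.0:
        phi = config.ar_coef
        noise[:, 0, :] /= np.sqrt(1 - phi**2)
        for t in range(1, n_times):
            noise[:, t, :] += phi * noise[:, t - 1, :]
        noise *= np.sqrt(1 - phi**2)  # keep unit marginal variance
    noise = np.einsum("ntc,dc->ndt", noise, chol, optimize=True)
    epochs = signal + config.noise_sd * noise

    return SubjectDataset(
        subject_id=int(subject_id),
        epochs=epochs,
        times=config.times,
        channel_names=_channel_names(config),
        stimulus=table["stimulus"].to_numpy(),
        condition=table["condition"].to_numpy(),
        response=table["response"].to_numpy(),
        latent_strength=latent,
        session=table["session"].to_numpy(),
        block=table["block"].to_numpy(),
        mode=config.mode,
        config_json=config.to_json(),
    )


def generate_cohort(
    config: GeneratorConfig, n_subjects: int | None = None
) -> list[SubjectDataset]:
    """Generate independent subjects sharing the cohort spatial structure."""
    n = config.n_subjects if n_subjects is None else int(n_subjects)
    return [generate_subject(config, sid) for sid in range(n)]


def behavioral_table(ds: SubjectDataset) -> pd.DataFrame:
    """Canonical one-row-per-trial table, stable trial ordering."""
    return pd.DataFrame(
        {
            "subject": ds.subject_id,
            "session": ds.session,
            "block": ds.block,
            "condition": ds.condition,
            "stimulus": ds.stimulus,
            "response": ds.response,
            "rt": np.nan,
        }
    )


def write_dataset(ds: SubjectDataset, path) -> None:
    """Write a subject dataset to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = ds.subject_id
        f.attrs["mode"] = ds.mode
        f.attrs["config_json"] = ds.config_json
        f.create_dataset("epochs", data=ds.epochs)
        f.create_dataset("times", data=ds.times)
        f.create_dataset("latent_strength", data=ds.latent_strength)
        f.create_dataset("response", data=ds.response.astype(np.int8))
        f.create_dataset("session", data=ds.session.astype(np.int16))
        f.create_dataset("block", data=ds.block.astype(np.int16))
        f.create_dataset("is_target", data=(ds.stimulus == "target"))
        f.create_dataset("is_conservative", data=(ds.condition == "conservative"))
        str_dt = h5py.string_dtype()
        f.create_dataset("channel_names", data=list(ds.channel_names), dtype=str_dt)


def read_dataset(path) -> SubjectDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises a clean error on schema-version mismatch or a corrupted file.
    """
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version", "<missing>")
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"schema version mismatch: file has {version!r}, "
                    f"expected {SCHEMA_VERSION!r}"
                )
            return SubjectDataset(
                subject_id=int(f.attrs["subject_id"]),
                epochs=f["epochs"][()],
                times=f["times"][()],
                channel_names=tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["channel_names"][()]
                ),
                stimulus=np.where(f["is_target"][()], "target", "no_target"),
                condition=np.where(
                    f["is_conservative"][()], "conservative", "liberal"
                ),
                response=f["response"][()].astype(int),
                latent_strength=f["latent_strength"][()],
                session=f["session"][()].astype(int),
                block=f["block"][()].astype(int),
                mode=str(f.attrs["mode"]),
                config_json=str(f.attrs.get("config_json", "")),
            )
    except OSError as err:
        raise OSError(f"cannot read dataset {path}: {err}") from err
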
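"""Tabular I/O, run configuration, and result serialization.

CSV conventions: results are written with 6 significant digits (EVPI values
are small, 0.0005-scale); the +infinity sentinel of the relative EVPI is
serialized as ``Inf`` and the undefined flag as an empty field, and both
round-trip through :func:`read_voi_csv`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .sample import DevelopmentSample
from .sampling import SamplingScheme

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "read_sample",
    "write_sample",
    "format_number",
    "write_voi_csv",
    "read_voi_csv",
    "write_optimism_csv",
    "write_sweep_csv",
    "write_diagnostics",
    "plot_decision_curves",
]

_TRUE = {"1", "yes", "y", "true"}
_FALSE = {"0", "no", "n", "false"}

_DEVELOPERS = ("logistic", "lasso", "intercept_only")


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Input data violates the expected schema."""


@dataclasses.dataclass
class RunConfig:
    """Configuration for a CLI run.

    ``transforms`` maps a predictor column to a transform spec, e.g.
    ``{"sysbp": ("truncate_above", 100.0), "pulse": ("linear_spline", 50.0)}``.
    ``thresholds`` of ``None`` means the default 0.00-0.99 grid.
    """

    input_path: str | Path
    outcome: str
    predictors: list[str] | None = None
    transforms: dict[str, tuple] | None = None
    thresholds: list[float] | None = None
    scheme: str = SamplingScheme.BAYESIAN_BOOTSTRAP.value
    developer: str = "logistic"
    n_draws: int = 1000
    n_boot: int = 1000
    seed: int = 1
    min_events: int = 1
    out_dir: str | Path = "."
    plot: bool = False

    def validate(self) -> "RunConfig":
        try:
            SamplingScheme(self.scheme)
        except ValueError:
            raise ConfigError(
                f"unknown scheme {self.scheme!r}; choose from "
                f"{[s.value for s in SamplingScheme]}"
            ) from None
        if self.developer not in _DEVELOPERS:
            raise ConfigError(
                f"unknown developer {self.developer!r}; choose from {_DEVELOPERS}"
            )
        if self.n_draws < 2:
            raise ConfigError("n_draws must be >= 2")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if self.min_events < 1:
            raise ConfigError("min_events must be >= 1")
        if self.thresholds is not None:
            for z in self.thresholds:
                if not 0.0 <= z <= 0.99:
                    raise ConfigError(f"threshold {z} outside [0, 0.99]")
        return self

    def build_developer(self, rng=None):
        from .developers import (
            InterceptOnlyDeveloper,
            LassoLogisticDeveloper,
            LogisticDeveloper,
        )

        return {
            "logistic": LogisticDeveloper,
            "lasso": LassoLogisticDeveloper,
            "intercept_only": InterceptOnlyDeveloper,
        }[self.developer]()

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(d["input_path"])
        d["out_dir"] = str(d["out_dir"])
        if d["transforms"]:
            d["transforms"] = {k: list(v) for k, v in d["transforms"].items()}
        return d


def _map_outcome(series: pd.Series) -> np.ndarray:
    out = np.empty(len(series), dtype=np.int64)
    for i, v in enumerate(series):
        if pd.isna(v):
            raise DataError(f"outcome missing in row {i}")
        s = str(v).strip().lower()
        if s in _TRUE or s == "1.0":
            out[i] = 1
        elif s in _FALSE or s == "0.0":
            out[i] = 0
        else:
            raise DataError(
                f"outcome value {v!r} in row {i} is not binary "
                "(expected 0/1 or yes/no)"
            )
    return out


def read_sample(
    path,
    outcome: str,
    predictors: list[str] | None = None,
    transforms: dict[str, tuple] | None = None,
) -> tuple[DevelopmentSample, dict]:
    """Read a development sample from a headered CSV.

    Categorical (non-numeric) predictors are one-hot encoded against an
    alphabetical reference level; transforms are applied afterwards to the
    named numeric columns.  Missing values raise :class:`DataError` (no
    imputation is implemented).  Returns the sample and a metadata dict
    recording column encodings, with row order preserved.
    """
    from .simulate import apply_transform

    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise DataError(f"outcome column {outcome!r} not in {list(df.columns)}")
    pred_cols = (
        [c for c in df.columns if c != outcome] if predictors is None else predictors
    )
    missing = [c for c in pred_cols if c not in df.columns]
    if missing:
        raise DataError(f"predictor column(s) {missing} not found")
    y = _map_outcome(df[outcome])

    meta: dict = {"outcome": outcome, "reference_levels": {}, "columns": []}
    pieces: dict[str, np.ndarray] = {}
    for col in pred_cols:
        s = df[col]
        if s.isna().any():
            row = int(s.isna().idxmax())
            raise DataError(f"missing value in predictor {col!r} at row {row}")
        if pd.api.types.is_numeric_dtype(s):
            pieces[col] = s.to_numpy(dtype=float)
        else:
            levels = sorted(map(str, s.unique()))
            ref = levels[0]
            meta["reference_levels"][col] = ref
            for lev in levels[1:]:
                pieces[f"{col}={lev}"] = (s.astype(str) == lev).to_numpy(float)
    if transforms:
        for col, spec in transforms.items():
            if col not in pieces:
                raise ConfigError(f"transform names unknown column {col!r}")
            base = pieces.pop(col)
            basis = apply_transform(base, tuple(spec))
            if len(basis) == 1:
                pieces[col] = basis[0]
            else:
                pieces[col] = basis[0]
                pieces[f"{col}_gt{spec[1]:g}"] = basis[1]
    design = pd.DataFrame(pieces)
    meta["columns"] = list(design.columns)
    return DevelopmentSample(design, y), meta


def write_sample(sample: DevelopmentSample, path) -> None:
    """Write covariates + outcome (column ``outcome``) as CSV."""
    df = sample.covariates.copy()
    df["outcome"] = sample.outcomes
    df.to_csv(path, index=False)


def format_number(x) -> str:
    """6-significant-digit formatting with Inf/undefined conventions."""
    if x is None:
        return ""
    xf = float(x)
    if math.isnan(xf):
        return ""
    if math.isinf(xf):
        return "Inf" if xf > 0 else "-Inf"
    return f"{xf:.6g}"


def _write_formatted_csv(df: pd.DataFrame, path) -> None:
    formatted = df.copy()
    for col in formatted.columns:
        if pd.api.types.is_float_dtype(formatted[col]):
            formatted[col] = formatted[col].map(format_number)
    formatted.to_csv(path, index=False)


def write_voi_csv(result, path) -> None:
    """One row per threshold; schema: threshold, nb_model_bar, nb_all_bar,
    nb_max_bar, evpi, evpi_r, delta_current, delta_perfect, mc_se,
    best_strategy."""
    _write_formatted_csv(result.to_frame(), path)


def read_voi_csv(path) -> pd.DataFrame:
    """Read a voi_results.csv back; 'Inf' -> inf, empty -> nan."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col == "best_strategy":
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_optimism_csv(report, path) -> None:
    _write_formatted_csv(report.to_frame(), path)


def write_sweep_csv(table: pd.DataFrame, path) -> None:
    _write_formatted_csv(table, path)


def write_diagnostics(path, *, config: RunConfig | None = None, **info) -> None:
    """JSON diagnostics: config echo, seeds, draw counts, warnings."""
    payload = dict(info)
    if config is not None:
        payload["config"] = config.to_jsonable()
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def plot_decision_curves(result, path, *, optimism_report=None) -> None:
    """Decision-curve and EVPI panels (headless-safe, optional).

    Top: posterior-mean NB of model / treat-all / treat-none (plus the
    optimism-corrected empirical curve when a report is given).  Bottom:
    incremental NB under current vs. perfect information, and EVPI.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = result.thresholds
    fig, axes = plt.subplots(3, 1, figsize=(7, 10), sharex=True)
    ax = axes[0]
    ax.plot(z, result.nb_model_bar, color="tab:blue", label="model (posterior mean)")
    ax.plot(z, result.nb_all_bar, color="black", label="treat all")
    ax.axhline(0.0, color="gray", lw=1, label="treat none")
    if optimism_report is not None:
        ax.plot(
            optimism_report.thresholds,
            optimism_report.corrected_nb,
            color="tab:red",
            label="model (optimism-corrected)",
        )
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=-0.05)
    ax.legend(frameon=False)

    ax = axes[1]
    ax.plot(z, result.delta_current, color="black", label="current information")
    ax.plot(z, result.delta_perfect, color="tab:red", label="perfect information")
    ax.set_ylabel("incremental net benefit")
    ax.legend(frameon=False)

    ax = axes[2]
    ax.plot(z, result.evpi, color="tab:purple")
    ax.set_ylabel("EVPI")
    ax.set_xlabel("risk threshold")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
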
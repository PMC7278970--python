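"""Table and configuration I/O.

Survival tables are comma-separated text with a mandatory header:
``cell_line, dose_Gy, dmso_M, oxygen, survival[, survival_err]`` with
``oxygen`` one of ``normoxic``/``hypoxic``.  Units are baked into the column
names (Gy, molar) so they cannot be silently mistaken.  Configuration is a
flat key-value document (YAML mapping, one level); unknown keys are errors
so a misspelled constant cannot pass silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import pandas as pd
import yaml

from .inference import SurvivalDataset, SurvivalRecord
from .model import DEFAULT_N_SAMPLES, DEFAULT_SEED

__all__ = [
    "RunConfig",
    "load_config",
    "read_survival_table",
    "write_survival_table",
    "write_predictions",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_line", "dose_Gy", "dmso_M", "oxygen", "survival")
OPTIONAL_COLUMNS = ("survival_err",)
_ALLOWED_OXYGEN = ("normoxic", "hypoxic")


@dataclass(frozen=True)
class RunConfig:
    """Global constants and run settings, all defaulting to the fitted values."""

    alpha_dsb: float = 5e-3
    dna_content: float = 6000.0
    loop_size: float = 2.0
    a_dmso: float = 0.9065
    b_dmso: float = 0.4172
    fr_dir: float = 0.20
    m: float = 2.94
    k_turn: float = 0.129
    registry_path: str | None = None
    seed: int = DEFAULT_SEED
    n_samples: int = DEFAULT_N_SAMPLES
    output_path: str | None = None


def load_config(path: str | Path | None) -> RunConfig:
    """Load a flat key-value config; ``None`` yields pure defaults.

    Any key overriding a default is logged at load time; unknown keys raise.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(known)}"
        )
    for key, value in raw.items():
        default = getattr(cfg, key)
        if value != default:
            logger.info("config override: %s = %r (default %r)", key, value, default)
    return replace(cfg, **raw)


def read_survival_table(path: str | Path) -> SurvivalDataset:
    """Read and validate a survival table; errors carry the offending row number.

    Row numbers refer to the data rows of the file, starting at 1 below the
    header.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}"
        )
    has_err = "survival_err" in df.columns
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 1
        try:
            oxygen = str(row["oxygen"]).strip()
            if oxygen not in _ALLOWED_OXYGEN:
                raise ValueError(
                    f"oxygen must be one of {list(_ALLOWED_OXYGEN)}, got {oxygen!r}"
                )
            err = None
            if has_err and pd.notna(row["survival_err"]):
                err = float(row["survival_err"])
            records.append(
                SurvivalRecord(
                    cell_line=str(row["cell_line"]).strip(),
                    dose=float(row["dose_Gy"]),
                    dmso_conc=float(row["dmso_M"]),
                    oxygen=oxygen,
                    surviving_fraction=float(row["survival"]),
                    uncertainty=err,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, data row {rownum}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: table contains no data rows")
    return SurvivalDataset(tuple(records))


def _dataset_frame(dataset: SurvivalDataset) -> pd.DataFrame:
    rows = []
    for r in dataset:
        rows.append(
            {
                "cell_line": r.cell_line,
                "dose_Gy": r.dose,
                "dmso_M": r.dmso_conc,
                "oxygen": r.oxygen,
                "survival": r.surviving_fraction,
                "survival_err": r.uncertainty if r.uncertainty is not None else "",
            }
        )
    return pd.DataFrame(rows)


def write_survival_table(dataset: SurvivalDataset, path: str | Path) -> None:
    """Write a dataset in the canonical table format (10 significant digits)."""
    _dataset_frame(dataset).to_csv(path, index=False, float_format="%.10g")


def write_predictions(
    dataset: SurvivalDataset,
    predictions: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write observed records side by side with model outputs.

    ``predictions`` must carry columns ``predicted_survival``,
    ``expected_dsb``, ``f_dmso`` and ``hrf_applied`` aligned with the
    dataset's records.  The output mirrors the input columns and
    round-trips through :func:`read_survival_table` at 10 significant
    digits.
    """
    required = ("predicted_survival", "expected_dsb", "f_dmso", "hrf_applied")
    missing = [c for c in required if c not in predictions.columns]
    if missing:
        raise ValueError(f"predictions frame is missing column(s) {missing}")
    if len(predictions) != len(dataset):
        raise ValueError(
            f"predictions has {len(predictions)} rows for {len(dataset)} records"
        )
    out = pd.concat(
        [_dataset_frame(dataset), predictions.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, index=False, float_format="%.10g")
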
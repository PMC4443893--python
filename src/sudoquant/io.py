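"""Cohort CSV reading/writing, result tables, and run-metadata echoes."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict
from .errors import InputError
from .pad_quant import QuantResult
from .synth import MEASURE_ANCHORS

logger = logging.getLogger(__name__)

#: columns parsed as numeric measures when present
NUMERIC_COLUMNS = tuple(MEASURE_ANCHORS) + ("latent_severity", "dpn")

_MISSING_MARKERS = ["", "NA", "NaN", "nan", "...", "…"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a subject-level cohort table.

    The mandatory column is ``neuropad_percent``; every measure column is
    individually optional and missing cells stay missing (NaN), never
    zero.  Unknown columns are carried through untouched.  A non-numeric
    entry in a numeric column raises :class:`InputError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    df = pd.read_csv(path, na_values=_MISSING_MARKERS, keep_default_na=True)
    if "neuropad_percent" not in df.columns:
        raise InputError(
            f"{path}: mandatory column 'neuropad_percent' is missing"
        )
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise InputError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        df[col] = coerced
    n_missing = int(df[[c for c in NUMERIC_COLUMNS if c in df.columns]].isna().sum().sum())
    logger.info("%s: %d subjects, %d missing measurement cells", path, len(df), n_missing)
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(Path(path), index=False)


def write_quant_results(results: Sequence[QuantResult], path: str | Path) -> pd.DataFrame:
    """Write one CSV row per quantified image; returns the table."""
    table = pd.DataFrame([r.to_row() for r in results])
    table.to_csv(Path(path), index=False)
    return table


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_metadata(
    out_path: str | Path,
    cfg: RunConfig,
    inputs: Iterable[str | Path] = (),
    seed: int | None = None,
) -> None:
    """Echo everything needed to reproduce a run next to its outputs.

    The payload (effective config, tool version, seed, input digests) is
    deterministic: no timestamps, so identical runs write identical bytes.
    """
    meta = {
        "tool": "sudoquant",
        "version": __version__,
        "seed": cfg.seed if seed is None else seed,
        "config": config_to_dict(cfg),
        "inputs": {str(p): sha256_digest(p) for p in inputs},
    }
    Path(out_path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
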
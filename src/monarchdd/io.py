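"""CSV/TSV round-tripping for trials, site records, summaries and results.

All tables are plain UTF-8 CSV with required headers; validation collects
per-row errors (with 1-based data row numbers) and reports them together.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .kvalue import EggLayingTrial
from .reduction import FieldDensitySummary, ReductionEstimate, SiteSurveyRecord
from .survival import LarvalTrial

EGG_TRIAL_COLUMNS = [
    "replicate_id", "n_females", "n_plants", "total_eggs",
    "cloud_cover_pct", "mean_age_days",
]
LARVAL_TRIAL_COLUMNS = ["replicate_id", "initial_eggs", "n_plants", "n_eclosed"]
SITE_COLUMNS = [
    "site_id", "region", "phase", "n_plants", "n_eggs",
    "n_instar1", "n_instar2", "n_instar3", "n_instar4", "n_instar5",
]
SUMMARY_COLUMNS = [
    "region", "phase", "stage_set", "mean_density", "se_density", "n_sites",
]
RESULT_COLUMNS = [
    "region", "phase", "stage_set", "mode", "mean_pct", "se_pct", "sd_pct",
    "raw_mean_pct", "n_draws", "seed",
]


class TableValidationError(ValueError):
    """One or more rows (or the header) of an input table are invalid."""

    def __init__(self, path, errors: Sequence[str]):
        self.errors = list(errors)
        msg = f"{path}: " + "; ".join(self.errors[:20])
        if len(self.errors) > 20:
            msg += f"; ... ({len(self.errors)} errors total)"
        super().__init__(msg)


def _load(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(path, [f"missing columns: {missing}"])
    if df.empty:
        raise TableValidationError(path, ["no records"])
    return df


def _collect(path, rows):
    """Build records, gathering row-level errors; raise if any."""
    records, errors = [], []
    for i, builder in rows:
        try:
            records.append(builder())
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise TableValidationError(path, errors)
    return records


def _opt_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_egg_trials(path) -> list[EggLayingTrial]:
    df = _load(path, EGG_TRIAL_COLUMNS[:4])
    rows = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def build(row=row):
            return EggLayingTrial(
                replicate_id=str(row["replicate_id"]),
                n_females=int(row["n_females"]),
                n_plants=int(row["n_plants"]),
                total_eggs=int(row["total_eggs"]),
                cloud_cover_pct=_opt_float(row.get("cloud_cover_pct")),
                mean_age_days=_opt_float(row.get("mean_age_days")),
            )
        rows.append((i, build))
    return _collect(path, rows)


def read_larval_trials(path) -> list[LarvalTrial]:
    df = _load(path, LARVAL_TRIAL_COLUMNS)
    rows = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def build(row=row):
            return LarvalTrial(
                replicate_id=str(row["replicate_id"]),
                initial_eggs=int(row["initial_eggs"]),
                n_plants=int(row["n_plants"]),
                n_eclosed=int(row["n_eclosed"]),
            )
        rows.append((i, build))
    return _collect(path, rows)


def read_site_records(path) -> list[SiteSurveyRecord]:
    df = _load(path, SITE_COLUMNS)
    rows = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def build(row=row):
            return SiteSurveyRecord(
                site_id=str(row["site_id"]),
                region=str(row["region"]),
                phase=str(row["phase"]),
                n_plants=int(row["n_plants"]),
                n_eggs=int(row["n_eggs"]),
                n_instar1=int(row["n_instar1"]),
                n_instar2=int(row["n_instar2"]),
                n_instar3=int(row["n_instar3"]),
                n_instar4=int(row["n_instar4"]),
                n_instar5=int(row["n_instar5"]),
            )
        rows.append((i, build))
    return _collect(path, rows)


def read_summaries(path) -> list[FieldDensitySummary]:
    df = _load(path, SUMMARY_COLUMNS[:5])
    rows = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def build(row=row):
            n_sites = row.get("n_sites")
            n_sites = None if n_sites is None or (
                isinstance(n_sites, float) and math.isnan(n_sites)
            ) else int(n_sites)
            return FieldDensitySummary(
                region=str(row["region"]),
                phase=str(row["phase"]),
                stage_set=str(row["stage_set"]),
                mean_density=float(row["mean_density"]),
                se_density=float(row["se_density"]),
                n_sites=n_sites,
            )
        rows.append((i, build))
    return _collect(path, rows)


def write_egg_trials(trials: Sequence[EggLayingTrial], path) -> None:
    pd.DataFrame(
        [{c: getattr(t, c) for c in EGG_TRIAL_COLUMNS} for t in trials]
    ).to_csv(path, index=False)


def write_larval_trials(trials: Sequence[LarvalTrial], path) -> None:
    pd.DataFrame(
        [{c: getattr(t, c) for c in LARVAL_TRIAL_COLUMNS} for t in trials]
    ).to_csv(path, index=False)


def write_site_records(records: Sequence[SiteSurveyRecord], path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in SITE_COLUMNS} for r in records]
    ).to_csv(path, index=False)


def write_summaries(summaries: Sequence[FieldDensitySummary], path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in SUMMARY_COLUMNS} for s in summaries]
    ).to_csv(path, index=False)


def write_results(estimates: Sequence[ReductionEstimate], path) -> None:
    """Write reduction estimates as TSV (full float precision)."""
    pd.DataFrame(
        [{c: getattr(e, c) for c in RESULT_COLUMNS} for e in estimates]
    ).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
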
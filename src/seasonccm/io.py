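"""CSV/JSON reading and writing for records, series and study reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .prep import SeasonalSeries, get_season
from .pipeline import StudyReport

RECORD_COLUMNS = ["year", "month", "region", "taxon", "abundance_m3"]

__all__ = [
    "read_records",
    "write_records",
    "read_series",
    "write_series",
    "write_report",
]


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a survey record table, validating columns, months and signs."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not df["month"].between(1, 12).all():
        raise ValueError(f"{path}: months must lie in 1..12")
    if (df["abundance_m3"] < 0).any():
        raise ValueError(f"{path}: abundances must be non-negative")
    return df[RECORD_COLUMNS]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def write_series(series: SeasonalSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(
    path: str | Path,
    taxon: str = "",
    region: str = "",
    season: str = "spring",
) -> SeasonalSeries:
    df = pd.read_csv(path)
    return SeasonalSeries(
        taxon=taxon,
        region=region,
        season=get_season(season),
        years=df["year"].to_numpy(),
        values=df["value"].to_numpy(),
        interpolated=df.get("interpolated", pd.Series(False, index=df.index))
        .to_numpy()
        .astype(bool),
    )


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Serialize a study report: hypothesis table, BRT influences, CCM curves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(outdir / "fig4_table.csv", index=False)

    rows = []
    for (region, role), res in report.brt.items():
        for name in res.predictor_names:
            rows.append(
                {
                    "region": region,
                    "response": role,
                    "predictor": name,
                    "influence_selection_pct": res.influence_selection[name],
                    "influence_improvement_pct": res.influence_improvement[name],
                    "learning_rate": res.learning_rate,
                    "tree_complexity": res.tree_complexity,
                    "n_trees": res.n_trees,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "fig3_influence.csv", index=False)

    curves = {f"{region}|{label}": c for (region, label), c in report.ccm_curves.items()}
    with open(outdir / "ccm_curves.json", "w") as fh:
        json.dump(curves, fh, indent=1, default=float)

    pd_rows = []
    for (region, role), res in report.brt.items():
        for name, (grid, curve) in res.partial_dependence.items():
            for g, v in zip(grid, curve):
                pd_rows.append(
                    {"region": region, "response": role, "predictor": name,
                     "value": g, "partial_dependence": v}
                )
    pd.DataFrame(pd_rows).to_csv(outdir / "partial_dependence.csv", index=False)
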
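"""Population summaries of a simulated exposure distribution.

Exposure is reported as percentile tables over the pooled
person x replicate values (rows: product group x population, columns
P25...P99), as histograms or cumulative distribution curves, and as the
fraction of the population exceeding a health-based limit (e.g. an
acceptable exposure level, AEL).  Report generation is a pure function of
the simulation result and the reporting options, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import ConfigurationError, SimulationResult

__all__ = [
    "PERCENTILE_LEVELS",
    "percentile_table",
    "format_percentile_table",
    "exceedance_fraction",
    "export_distribution",
    "plot_distribution",
    "write_report",
]

PERCENTILE_LEVELS = (25, 50, 75, 90, 95, 99)


def _populations(sex: str) -> list[str]:
    if sex == "both":
        return ["men", "women", "both"]
    if sex in ("men", "women"):
        return [sex]
    raise ConfigurationError(f"unknown sex filter {sex!r}")


def percentile_table(
    result: SimulationResult,
    time_frame: str = "highest",
    sex: str = "both",
    exposed_only: bool = False,
    levels: Sequence[float] = PERCENTILE_LEVELS,
) -> pd.DataFrame:
    """Percentile table of the pooled person x replicate exposures.

    One row per (product group, population); groups are the run's PCP/HCP
    selections plus their Total.  Percentiles use linear interpolation
    between order statistics.  With ``exposed_only`` persons with zero
    exposure on every simulated day in every replicate are excluded.
    """
    rows = []
    for group in result.groups:
        for pop in _populations(sex):
            vals = result.values(
                group=group, time_frame=time_frame, sex=pop, exposed_only=exposed_only
            )
            pcts = np.percentile(vals, levels)
            rows.append([group, pop, *pcts])
    table = pd.DataFrame(
        rows, columns=["product_group", "population", *[f"P{int(l)}" for l in levels]]
    )
    return table.set_index(["product_group", "population"])


def format_percentile_table(table: pd.DataFrame, display_floor: float = 0.0) -> pd.DataFrame:
    """Render a percentile table for display: values at or below the
    display floor are shown as 0, others in scientific notation."""
    def fmt(v: float) -> str:
        return "0" if v <= display_floor else f"{v:.2g}"

    return table.map(fmt)


def exceedance_fraction(
    result: SimulationResult,
    threshold: float,
    group: str = "Total",
    time_frame: str = "highest",
    sex: str = "both",
    exposed_only: bool = False,
) -> float:
    """Fraction of the filtered person x replicate values strictly above
    the threshold (e.g. an AEL)."""
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    vals = result.values(
        group=group, time_frame=time_frame, sex=sex, exposed_only=exposed_only
    )
    return float((vals > threshold).mean())


def export_distribution(
    result: SimulationResult,
    kind: str = "histogram",
    bins: int = 50,
    group: str = "Total",
    time_frame: str = "highest",
    sex: str = "both",
    exposed_only: bool = False,
) -> pd.DataFrame:
    """Plot-ready histogram (bin edges + counts) or empirical CDF table."""
    vals = result.values(
        group=group, time_frame=time_frame, sex=sex, exposed_only=exposed_only
    )
    if kind == "histogram":
        counts, edges = np.histogram(vals, bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
    if kind == "cdf":
        x = np.sort(vals)
        return pd.DataFrame(
            {"value": x, "cum_prob": np.arange(1, len(x) + 1) / len(x)}
        )
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


def plot_distribution(
    result: SimulationResult,
    kind: str = "histogram",
    out: str | Path | None = None,
    **options,
):
    """Matplotlib rendering of the histogram or CDF (convenience; the CSV
    tables from :func:`export_distribution` are the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = export_distribution(result, kind=kind, **options)
    fig, ax = plt.subplots(figsize=(6, 4))
    if kind == "histogram":
        widths = table["bin_right"] - table["bin_left"]
        ax.bar(table["bin_left"], table["count"], width=widths, align="edge")
        ax.set_ylabel("persons x replicates")
    else:
        ax.step(table["value"], table["cum_prob"], where="post")
        ax.set_ylabel("cumulative probability")
    ax.set_xlabel(f"exposure ({result.units})")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def write_report(
    result: SimulationResult,
    outdir: str | Path,
    time_frame: str = "highest",
    sex: str = "both",
    exposed_only: bool = False,
    config_digest: str | None = None,
) -> dict[str, Path]:
    """Write the standard report bundle: per-person summary CSV, percentile
    table CSV and a JSON run manifest.  Pure function of result + options."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = result.to_frame(group="Total", time_frame=time_frame)
    paths["persons"] = outdir / "person_summaries.csv"
    frame.to_csv(paths["persons"], index=False, float_format="%.10g", lineterminator="\n")

    table = percentile_table(
        result, time_frame=time_frame, sex=sex, exposed_only=exposed_only
    )
    paths["percentiles"] = outdir / "percentiles.csv"
    table.to_csv(paths["percentiles"], float_format="%.10g", lineterminator="\n")

    manifest = {
        "metric": result.metric,
        "units": result.units,
        "n_persons": int(len(result.persons)),
        "n_product": int(result.n_product),
        "seed": int(result.seed),
        "time_frame": time_frame,
        "sex": sex,
        "exposed_only": bool(exposed_only),
        "config_sha256": config_digest,
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
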
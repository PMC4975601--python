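"""Report writers and the run manifest.

Every CLI subcommand writes its data products (CSV for tables, JSON for
summaries) and a manifest listing each output file with its SHA-256 content
hash, the seed and the package version.  Deterministic subcommands rerun
with an identical config and seed reproduce identical content hashes; the
manifest timestamp is informational and excluded from the hashed content.
"""

from __future__ import annotations

import csv
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

from .cost_engine import CostBreakdown
from .regression import LinearFit
from .sensitivity import TornadoRow
from .uncertainty import MCResult

__all__ = [
    "write_breakdown",
    "write_tornado",
    "write_mc",
    "write_fit",
    "write_manifest",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    outputs: Iterable[str | Path],
    *,
    seed: int | None = None,
    config_files: Iterable[str | Path] = (),
) -> Path:
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "configs": {str(p): _sha256(Path(p)) for p in config_files},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_breakdown(bd: CostBreakdown, outdir: str | Path, stem: str = "breakdown") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section", "name", "annual_cost_usd"])
        for name, cost in bd.by_category.items():
            w.writerow(["category", name, f"{cost:.2f}"])
        for name, cost in bd.by_unit_operation.items():
            w.writerow(["unit_operation", name, f"{cost:.2f}"])
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(
        {
            "by_category": bd.by_category,
            "by_unit_operation": bd.by_unit_operation,
            "total_usd_per_yr": bd.total,
            "annual_mass_g": bd.annual_mass,
            "cog_per_gram_usd": bd.cog_per_gram,
            "batches": bd.batches,
            "trains_used": bd.trains_used,
            "capacity_expanded": bd.capacity_expanded,
        },
        indent=2, sort_keys=True,
    ))
    return [csv_path, json_path]


def write_tornado(rows: list[TornadoRow], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "tornado.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "rank", "parameter", "cog_worst", "cog_base", "cog_best",
            "delta_worst", "delta_best", "max_abs_delta",
            "expanded_worst", "expanded_best",
        ])
        for rank, r in enumerate(rows, start=1):
            w.writerow([
                rank, r.parameter, f"{r.cog_worst:.2f}", f"{r.cog_base:.2f}",
                f"{r.cog_best:.2f}", f"{r.delta_worst:.2f}", f"{r.delta_best:.2f}",
                f"{r.max_abs_delta:.2f}", r.expanded_worst, r.expanded_best,
            ])
    return path


def plot_tornado(rows: list[TornadoRow], path: str | Path) -> Path:
    """Optional horizontal-bar tornado figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.6 * len(rows) + 1.5))
    names = [r.parameter for r in rows][::-1]
    base = rows[0].cog_base
    for i, r in enumerate(rows[::-1]):
        ax.barh(i, r.cog_worst - base, left=base, color="#c0504d", height=0.6)
        ax.barh(i, r.cog_best - base, left=base, color="#4f81bd", height=0.6)
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("CoG/g (US$)")
    ax.set_title(f"One-at-a-time sensitivity (base CoG/g = ${base:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_mc(result: MCResult, outdir: str | Path, stem: str = "mc") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}_samples.csv"
    result.samples.to_csv(csv_path, index=False)
    json_path = outdir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(
        {
            "summary": result.summary,
            "runs": int(len(result.samples)),
            "runs_to_convergence": result.runs_to_convergence,
            "seed": result.seed,
            "n_capacity_expanded": result.n_capacity_expanded,
        },
        indent=2, sort_keys=True,
    ))
    return [csv_path, json_path]


def write_fit(fit: LinearFit, outdir: str | Path, stem: str = "fit") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    fit.to_frame().rename_axis("term").to_csv(csv_path)
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(
        {
            "coefficients": fit.coefficients,
            "standard_errors": fit.standard_errors,
            "t_statistics": fit.t_statistics,
            "p_values": fit.p_values,
            "residual_variance": fit.residual_variance,
            "n": fit.n,
            "df_resid": fit.df_resid,
        },
        indent=2, sort_keys=True,
    ))
    return [csv_path, json_path]
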
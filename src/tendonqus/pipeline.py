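"""End-to-end orchestration: extraction, group summaries, reliability reports.

The feature table format shared by every stage is a long-format CSV with
columns ``tendon_id, group, evaluator, visit, image, view, feature, value,
undefined`` -- one row per measurement per design cell.  The analysis unit
for summaries is the tendon: each tendon's measurements are first averaged
over its images, then group statistics are taken over tendons.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
from scipy import stats as sps

from . import gtheory
from .features import FeatureConfig, extract_features
from .gtheory import EFFECTS, estimate_variance_components, protocol_grid, variance_proportions
from .roi_io import PixelCalibration, load_image, load_roi, save_roi
from .synthetic import simulate_tendon_image

__all__ = [
    "GroupSummary",
    "run_extract",
    "group_summary",
    "percent_difference",
    "reliability_report",
    "main",
]

log = logging.getLogger("tendonqus")

DESIGN_COLUMNS = (
    "tendon_id", "group", "evaluator", "visit", "image", "view", "image_path", "roi_path",
)


@dataclass(frozen=True)
class GroupSummary:
    """Per feature x view x group descriptive statistics."""

    table: pd.DataFrame  # columns: view, feature, group, n, mean, sd, ci_lower, ci_upper
    differences: pd.DataFrame  # columns: view, feature, percent_difference

    def percent_difference(self, view: str, feature: str) -> float:
        d = self.differences
        row = d[(d["view"] == view) & (d["feature"] == feature)]
        if row.empty:
            raise KeyError((view, feature))
        return float(row["percent_difference"].iloc[0])


def percent_difference(symptomatic_mean: float, asymptomatic_mean: float) -> float:
    """Between-group difference as a percentage of the asymptomatic mean."""
    if asymptomatic_mean == 0:
        raise ValueError("asymptomatic mean is zero")
    return 100.0 * (symptomatic_mean - asymptomatic_mean) / asymptomatic_mean


def run_extract(
    design_csv: str | Path,
    image_dir: str | Path | None = None,
    roi_dir: str | Path | None = None,
    config: FeatureConfig | None = None,
    calibration: PixelCalibration | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract features for every row of a design table.

    Returns (feature table, failures); per-row failures are logged and
    collected rather than aborting the run.
    """
    design = pd.read_csv(design_csv)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    if design.empty:
        raise ValueError("design table is empty")
    image_dir = Path(image_dir) if image_dir else Path(design_csv).parent
    roi_dir = Path(roi_dir) if roi_dir else image_dir
    config = config or FeatureConfig()
    records: list[dict] = []
    failures: list[dict] = []
    for _, row in design.iterrows():
        try:
            image = load_image(
                image_dir / row["image_path"],
                calibration=calibration,
                view=row["view"],
                collapse_rgb=True,
            )
            roi = load_roi(roi_dir / row["roi_path"])
            fs = extract_features(image, roi, config)
        except Exception as exc:  # noqa: BLE001 - per-row isolation is the contract
            log.error("extraction failed for %s: %s", row["image_path"], exc)
            failures.append({**row.to_dict(), "error": str(exc)})
            continue
        for name in fs.feature_names:
            records.append(
                {
                    "tendon_id": row["tendon_id"],
                    "group": row["group"],
                    "evaluator": row["evaluator"],
                    "visit": row["visit"],
                    "image": row["image"],
                    "view": row["view"],
                    "feature": name,
                    "value": fs.values[name],
                    "undefined": name in fs.undefined,
                }
            )
    return pd.DataFrame.from_records(records), failures


def _ci(mean: float, sd: float, n: int, method: str) -> tuple[float, float]:
    if n < 2:
        return mean, mean
    if method == "t":
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    else:
        half = 1.96 * sd / math.sqrt(n)
    return mean - half, mean + half


def group_summary(features: pd.DataFrame, ci_method: str = "normal") -> GroupSummary:
    """Tendon-level means, then per-group mean/SD/95% CI and group differences."""
    df = features.copy()
    if "undefined" in df.columns:
        df = df[~df["undefined"].astype(bool)]
    if df.empty:
        raise ValueError("no defined feature records")
    view_col = "view" if "view" in df.columns else None
    keys = ["feature", "tendon_id", "group"] + ([view_col] if view_col else [])
    per_tendon = df.groupby(keys, as_index=False)["value"].mean()
    if not view_col:
        per_tendon["view"] = "unknown"
    rows, diffs = [], []
    for (view, feature), sub in per_tendon.groupby(["view", "feature"]):
        means = {}
        for group, gsub in sub.groupby("group"):
            vals = gsub["value"].to_numpy()
            n = len(vals)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            lo, hi = _ci(mean, sd, n, ci_method)
            rows.append(
                dict(view=view, feature=feature, group=group, n=n,
                     mean=mean, sd=sd, ci_lower=lo, ci_upper=hi)
            )
            means[group] = mean
        if "symptomatic" in means and "asymptomatic" in means and means["asymptomatic"] != 0:
            diffs.append(
                dict(view=view, feature=feature,
                     percent_difference=percent_difference(means["symptomatic"], means["asymptomatic"]))
            )
    return GroupSummary(
        table=pd.DataFrame(rows), differences=pd.DataFrame(diffs, columns=["view", "feature", "percent_difference"])
    )


def reliability_report(
    features: pd.DataFrame,
    protocols: tuple[tuple[int, int, int], ...] = gtheory.DEFAULT_PROTOCOLS,
    z: float = gtheory.Z_90,
) -> dict[str, pd.DataFrame]:
    """G-study proportions and D-study grid per feature x view x group.

    Feature x group analyses containing undefined values or unbalanced
    designs are skipped with a logged reason; the rest of the report is
    still produced.
    """
    df = features.copy()
    if "view" not in df.columns:
        df["view"] = "unknown"
    prop_rows, grid_rows, skipped = [], [], []
    for (view, feature, group), sub in df.groupby(["view", "feature", "group"]):
        if "undefined" in sub.columns and sub["undefined"].astype(bool).any():
            skipped.append(dict(view=view, feature=feature, group=group, reason="undefined values"))
            log.warning("skipping %s/%s/%s: undefined values", view, feature, group)
            continue
        try:
            vc = estimate_variance_components(sub)
            props = variance_proportions(vc)
        except ValueError as exc:
            skipped.append(dict(view=view, feature=feature, group=group, reason=str(exc)))
            log.warning("skipping %s/%s/%s: %s", view, feature, group, exc)
            continue
        prop_rows.append(dict(view=view, feature=feature, group=group, **props))
        gmean = float(sub["value"].mean())
        for res in protocol_grid(vc, group_mean=gmean, protocols=protocols, z=z):
            grid_rows.append(
                dict(
                    view=view, feature=feature, group=group,
                    n_e=res.n_e, n_v=res.n_v, n_i=res.n_i,
                    phi=res.phi, sem=res.sem,
                    mdc_abs=res.mdc_abs, mdc_norm=res.mdc_norm,
                    interpretation=res.interpretation,
                )
            )
    return {
        "variance_proportions": pd.DataFrame(
            prop_rows, columns=["view", "feature", "group", *EFFECTS]
        ),
        "dstudy_grid": pd.DataFrame(
            grid_rows,
            columns=["view", "feature", "group", "n_e", "n_v", "n_i",
                     "phi", "sem", "mdc_abs", "mdc_norm", "interpretation"],
        ),
        "skipped": pd.DataFrame(skipped, columns=["view", "feature", "group", "reason"]),
    }


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Quantitative ultrasound measurement and reliability pipeline."""
    logging.basicConfig(level=log_level.upper(), stream=sys.stderr)


@main.command()
@click.argument("design_csv", type=click.Path(exists=True))
@click.option("--image-dir", type=click.Path(), default=None)
@click.option("--roi-dir", type=click.Path(), default=None)
@click.option("--out", type=click.Path(), default="features.csv", show_default=True)
@click.option("--distance", default=10, show_default=True)
@click.option("--entropy-mode", default="histogram", show_default=True)
def extract(design_csv, image_dir, roi_dir, out, distance, entropy_mode):
    """Extract the QUS measurements for every design row."""
    cfg = FeatureConfig(distance=distance, entropy_mode=entropy_mode)
    features, failures = run_extract(design_csv, image_dir, roi_dir, cfg)
    features.to_csv(out, index=False)
    click.echo(f"wrote {len(features)} records to {out}", err=True)
    if failures:
        click.echo(f"{len(failures)} design rows failed", err=True)
        sys.exit(1)


@main.command()
@click.argument("feature_csv", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default="summary.csv", show_default=True)
@click.option("--ci-method", default="normal", show_default=True, type=click.Choice(["normal", "t"]))
def summary(feature_csv, out, ci_method):
    """Group means, SDs, 95% CIs and between-group percent differences."""
    gs = group_summary(pd.read_csv(feature_csv), ci_method=ci_method)
    gs.table.to_csv(out, index=False)
    diff_path = Path(out).with_suffix(".differences.csv")
    gs.differences.to_csv(diff_path, index=False)
    click.echo(f"wrote {out} and {diff_path}", err=True)


@main.command()
@click.argument("feature_csv", type=click.Path(exists=True))
@click.option("--out-dir", type=click.Path(), default="reliability", show_default=True)
@click.option("--z", default=gtheory.Z_90, show_default=True)
def reliability(feature_csv, out_dir, z):
    """G-study variance proportions and D-study protocol grid."""
    report = reliability_report(pd.read_csv(feature_csv), z=z)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {}
    for name, table in report.items():
        table.to_csv(out / f"{name}.csv", index=False)
        bundle[name] = table.to_dict(orient="records")
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    click.echo(f"wrote report bundle to {out}", err=True)


@main.command()
@click.option("--out-dir", type=click.Path(), default="simulated", show_default=True)
@click.option("--n-subjects", default=4, show_default=True)
@click.option("--group", default="asymptomatic", show_default=True,
              type=click.Choice(["asymptomatic", "symptomatic"]))
@click.option("--view", default="longitudinal", show_default=True,
              type=click.Choice(["longitudinal", "transverse"]))
@click.option("--roi-jitter", default=2.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
def simulate(out_dir, n_subjects, group, view, roi_jitter, seed):
    """Emit a synthetic crossed study: images, ROI JSONs, design CSV, truth."""
    from .synthetic import healthy_params, pathologic_params

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = healthy_params if group == "asymptomatic" else pathologic_params
    rows = []
    for s in range(n_subjects):
        for e in (1, 2):
            for v in (1, 2):
                for i in (1, 2):
                    params = base(view=view, seed=int(rng.integers(0, 2**31 - 1)))
                    image, roi, truth = simulate_tendon_image(params)
                    stem = f"s{s:03d}_e{e}_v{v}_i{i}"
                    from PIL import Image as PILImage

                    PILImage.fromarray(image.pixels).save(out / f"{stem}.png")
                    save_roi(roi, out / f"{stem}.roi.json")
                    rows.append(
                        dict(tendon_id=f"T{s:03d}", group=group, evaluator=e, visit=v,
                             image=i, view=view, image_path=f"{stem}.png",
                             roi_path=f"{stem}.roi.json", **truth)
                    )
    design = pd.DataFrame(rows)
    design[list(DESIGN_COLUMNS)].to_csv(out / "design.csv", index=False)
    design.to_json(out / "truth.json", orient="records", indent=2)
    click.echo(f"wrote {len(rows)} cells to {out}", err=True)


if __name__ == "__main__":
    main()
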
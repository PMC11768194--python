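"""Batch pipeline: analyze images, curves and colour tables per group.

The pipeline reads a config (YAML or JSON) naming replicate inputs per
group, runs every analysis stage, and writes a report bundle:

- ``report.json`` -- config echo (with seed), per-sample results, group
  summaries; bit-identical across reruns with the same config and inputs
- ``tables/*.csv`` -- per-family mean ± SD with Tukey letters
- ``colourmaps/*.png`` -- per-image area-coded region renderings
- ``run_log.txt`` -- timestamped log (the only non-deterministic output)

Failures are isolated per sample: a bad input puts an entry into the
``errors`` list instead of aborting the whole run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from breadtex import io as btio
from breadtex.colorimetry import LabColor, average_readings, delta_e
from breadtex.crumb import (
    SizeClassConfig,
    classify_sizes,
    extract_regions,
    load_slice,
    render_colourmap,
    segment_pores,
)
from breadtex.groupstats import GroupData, tukey_letters, one_way_anova
from breadtex.mixolab import ExtractionConfig, extract_parameters
from breadtex.synthetic import (
    ChopinProtocol,
    CrumbSceneSpec,
    generate_color_readings,
    generate_crumb_image,
    generate_torque_curve,
)
from breadtex.mixolab import MixolabParameters

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "generate_demo_dataset"]

MIXOLAB_FAMILIES = (
    "t_hydr", "t1", "c1", "amplitude", "stability", "slope_alpha",
    "c2", "slope_beta", "c3", "t3", "gelling_mid", "c4", "c5",
)
PORE_FAMILIES = ("n_small", "n_medium", "n_large", "n_total", "porosity")
COLOR_FAMILIES = ("L", "a", "b")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    reference_group: Optional[str] = None
    images: dict[str, list[Path]] = field(default_factory=dict)
    curves: dict[str, list[Path]] = field(default_factory=dict)
    colors_csv: Optional[Path] = None
    background_mode: str = "white_threshold"
    size_classes: SizeClassConfig = field(default_factory=SizeClassConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path | str = ".") -> "PipelineConfig":
        base = Path(base_dir)

        def resolve(p: str) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        images = {
            g: [resolve(p) for p in paths] for g, paths in (raw.get("images") or {}).items()
        }
        curves = {
            g: [resolve(p) for p in paths] for g, paths in (raw.get("curves") or {}).items()
        }
        colors_csv = resolve(raw["colors_csv"]) if raw.get("colors_csv") else None
        return cls(
            out_dir=resolve(raw.get("out_dir", "breadtex_out")),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            reference_group=raw.get("reference_group"),
            images=images,
            curves=curves,
            colors_csv=colors_csv,
            background_mode=raw.get("background_mode", "white_threshold"),
            size_classes=SizeClassConfig(**(raw.get("size_classes") or {})),
            extraction=ExtractionConfig(**(raw.get("extraction") or {})),
        )

    def echo(self) -> dict[str, Any]:
        """JSON-serializable echo of the configuration, seed included."""
        return {
            "seed": self.seed,
            "alpha": self.alpha,
            "reference_group": self.reference_group,
            "background_mode": self.background_mode,
            "out_dir": str(self.out_dir),
            "images": {g: [str(p) for p in ps] for g, ps in sorted(self.images.items())},
            "curves": {g: [str(p) for p in ps] for g, ps in sorted(self.curves.items())},
            "colors_csv": str(self.colors_csv) if self.colors_csv else None,
            "size_classes": dataclasses.asdict(self.size_classes),
            "extraction": dataclasses.asdict(self.extraction),
        }


def _group_table(values: dict[str, dict[str, list[float]]], families, alpha: float):
    """Per-family mean ± SD + Tukey letters across groups.

    ``values[family][group]`` is the replicate list.  Families where
    inference is impossible (a group with < 2 replicates) get empty
    letters.
    """
    rows = []
    for family in families:
        per_group = values.get(family, {})
        if len(per_group) < 2:
            continue
        clean = {g: np.asarray(v, dtype=float) for g, v in per_group.items() if len(v) > 0}
        if len(clean) < 2:
            continue
        letters: dict[str, str] = {}
        f_stat = p_value = float("nan")
        if all(v.size >= 2 for v in clean.values()):
            data = GroupData(groups=clean)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p_value = one_way_anova(data)
                letters = tukey_letters(data, alpha=alpha).letters
        for g, v in clean.items():
            rows.append(
                {
                    "family": family,
                    "group": g,
                    "n": int(v.size),
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "letters": letters.get(g, ""),
                    "anova_F": f_stat,
                    "anova_p": p_value,
                }
            )
    return pd.DataFrame(
        rows, columns=["family", "group", "n", "mean", "sd", "letters", "anova_F", "anova_p"]
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage and write the report bundle.

    Returns the report dictionary (also written to ``report.json``).
    Raises :class:`PipelineError` when there is no input at all; per-sample
    failures are collected in ``report["errors"]``.
    """
    if not config.images and not config.curves and config.colors_csv is None:
        raise PipelineError("no inputs configured: need images, curves, or a colour table")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": config.echo(),
        "samples": {},
        "groups": {},
        "errors": [],
    }

    # --- crumb images ------------------------------------------------------
    pore_values: dict[str, dict[str, list[float]]] = {f: {} for f in PORE_FAMILIES}
    for group, paths in sorted(config.images.items()):
        for path in paths:
            sample_id = f"{group}/{Path(path).stem}"
            try:
                image = load_slice(path, background_mode=config.background_mode)
                labels = segment_pores(image, config.size_classes)
                regions = extract_regions(labels, image)
                stats = classify_sizes(regions, image.slice_area, config.size_classes)
                rendering = render_colourmap(labels, regions)
                btio.write_image_png(
                    rendering, out_dir / "colourmaps" / f"{group}_{Path(path).stem}.png"
                )
            except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
                report["errors"].append({"sample": sample_id, "stage": "crumb", "error": str(exc)})
                continue
            rec = {
                "n_small": stats.n_small,
                "n_medium": stats.n_medium,
                "n_large": stats.n_large,
                "n_total": stats.n_total,
                "porosity": stats.porosity,
                "mean_pore_area": stats.mean_pore_area,
                "pore_density": stats.pore_density,
            }
            report["samples"].setdefault(sample_id, {})["pores"] = rec
            for fam in PORE_FAMILIES:
                pore_values[fam].setdefault(group, []).append(float(rec[fam]))

    # --- torque curves -----------------------------------------------------
    mixo_values: dict[str, dict[str, list[float]]] = {f: {} for f in MIXOLAB_FAMILIES}
    for group, paths in sorted(config.curves.items()):
        for path in paths:
            sample_id = f"{group}/{Path(path).stem}"
            try:
                curve = btio.read_curve_csv(path)
                params = extract_parameters(curve, config.extraction)
            except Exception as exc:  # noqa: BLE001
                report["errors"].append({"sample": sample_id, "stage": "mixolab", "error": str(exc)})
                continue
            report["samples"].setdefault(sample_id, {})["mixolab"] = params.as_dict()
            for fam in MIXOLAB_FAMILIES:
                v = getattr(params, fam)
                if v is not None:
                    mixo_values[fam].setdefault(group, []).append(float(v))

    # --- colours -----------------------------------------------------------
    color_values: dict[str, dict[str, list[float]]] = {f: {} for f in COLOR_FAMILIES}
    color_report: dict[str, Any] = {}
    if config.colors_csv is not None:
        try:
            table = btio.read_color_csv(config.colors_csv)
        except Exception as exc:  # noqa: BLE001
            report["errors"].append({"sample": str(config.colors_csv), "stage": "color", "error": str(exc)})
            table = None
        if table is not None:
            group_means: dict[str, LabColor] = {}
            for group, sub in table.groupby("group", sort=True):
                readings = [
                    LabColor(L=row.L, a=row.a, b=row.b) for row in sub.itertuples()
                ]
                group_means[str(group)] = average_readings(readings)
                for fam in COLOR_FAMILIES:
                    color_values[fam][str(group)] = sub[fam].astype(float).tolist()
            reference = config.reference_group
            if reference is None and group_means:
                reference = sorted(group_means)[0]
            for group, mean in sorted(group_means.items()):
                entry: dict[str, Any] = {
                    "mean": {"L": mean.L, "a": mean.a, "b": mean.b},
                }
                if reference in group_means:
                    result = delta_e(group_means[reference], mean)
                    entry["delta_e"] = result.delta_e
                    entry["band"] = result.band_label
                color_report[group] = entry
            report["color"] = {"reference_group": reference, "groups": color_report}

    # --- group tables ------------------------------------------------------
    tables_dir = out_dir / "tables"
    for name, values, families in (
        ("pores", pore_values, PORE_FAMILIES),
        ("mixolab", mixo_values, MIXOLAB_FAMILIES),
        ("color", color_values, COLOR_FAMILIES),
    ):
        frame = _group_table(values, families, config.alpha)
        if not frame.empty:
            tables_dir.mkdir(parents=True, exist_ok=True)
            frame.to_csv(tables_dir / f"{name}.csv", index=False, float_format="%.12g")
            report["groups"][name] = frame.to_dict(orient="records")

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"run at {datetime.now(timezone.utc).isoformat()}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(json.dumps(report["config"], indent=2, sort_keys=True))
        fh.write("\n")
        for err in report["errors"]:
            fh.write(f"ERROR {err['sample']} [{err['stage']}]: {err['error']}\n")
    return report


# ---------------------------------------------------------------------------
# Demo fixture set
# ---------------------------------------------------------------------------

def generate_demo_dataset(root: str | Path, seed: int = 0) -> Path:
    """Write a small 3-group × 3-replicate fixture set plus its config.

    Returns the path of the generated ``config.yaml``.  Everything is
    derived from ``seed``, so two calls with the same arguments produce
    identical trees.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    groups = ["control", "blend10", "blend15"]
    protocol = ChopinProtocol()
    config: dict[str, Any] = {
        "seed": seed,
        "alpha": 0.05,
        "reference_group": "control",
        "out_dir": "out",
        "images": {},
        "curves": {},
        "colors_csv": "colors.csv",
    }

    base = MixolabParameters(
        t_hydr=3.6, t1=7.0, c1=1.10, water_absorption=62.8, amplitude=0.09,
        stability=6.9, c2=0.50, c3=1.62, t3=21.7, gelling_mid=66.0, c4=1.29, c5=1.90,
    )
    for gi, group in enumerate(groups):
        image_paths, curve_paths = [], []
        for rep in range(3):
            spec = CrumbSceneSpec(
                n_pores=28 + 8 * gi,
                noise_sd=5.0,
                seed=seed * 9973 + gi * 101 + rep,
            )
            image, _ = generate_crumb_image(spec)
            img_path = root / "images" / f"{group}_{rep + 1}.png"
            btio.write_image_png(image, img_path)
            image_paths.append(str(img_path.relative_to(root)))

            params = dataclasses.replace(
                base,
                c3=base.c3 + 0.06 * gi,
                c5=base.c5 + 0.1 * gi,
                gelling_mid=base.gelling_mid + 1.0 * gi,
                stability=base.stability + 0.12 * gi,
            )
            curve = generate_torque_curve(
                params, protocol, noise_sd=0.005, seed=seed * 7919 + gi * 97 + rep
            )
            curve_path = root / "curves" / f"{group}_{rep + 1}.csv"
            btio.write_curve_csv(curve, curve_path)
            curve_paths.append(str(curve_path.relative_to(root)))
        config["images"][group] = image_paths
        config["curves"][group] = curve_paths

    means = {
        group: LabColor(L=91.0 - 2.5 * gi, a=0.4 + 0.7 * gi, b=9.0 + 2.0 * gi)
        for gi, group in enumerate(groups)
    }
    readings = generate_color_readings(means, sd=0.3, n_replicates=3, seed=seed * 6007)
    btio.write_color_csv(readings, root / "colors.csv")

    config_path = root / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
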
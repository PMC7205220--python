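"""End-to-end orchestration: simulate a phantom study, measure depth and
coverage on every section, fit the age regressions, and write tables,
a human-readable report, and (on request) figures.

Every emitted figure is reconstructible from the emitted CSVs alone;
the CSVs are the tested surface. All randomness flows from the single
config seed, so reruns with identical inputs produce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig, save_config
from .coverage import (
    classify_red_dual,
    classify_white,
    partition_surface_regions,
    place_rois,
    roi_class_percentages,
)
from .depth import (
    align_series,
    compute_distance_map,
    measure_section_depth,
    section_depth_stats,
)
from .phantom import (
    SectionPhantomSpec,
    SineSurface,
    heart_dataset_from_series,
    make_heart_series,
)
from .section_io import HeartDataset, load_heart, write_heart, write_results
from .stats import anova_tukey, fit_model, format_p, summarize

logger = logging.getLogger(__name__)

_STUDY_JSON = "study.json"

AVN_REGION_SHARES = {"extension": 0.4, "compact": 0.3, "transition": 0.2, "his": 0.1}


def _avn_region_labels(n_sections: int) -> list[str]:
    counts = {r: max(1, round(s * n_sections)) for r, s in AVN_REGION_SHARES.items()}
    while sum(counts.values()) > n_sections:
        counts[max(counts, key=counts.get)] -= 1
    counts["his"] += n_sections - sum(counts.values())
    labels: list[str] = []
    for region in AVN_REGION_SHARES:
        labels.extend([region] * counts[region])
    return labels


def _clip01(x: float, lo: float = 0.05, hi: float = 0.95) -> float:
    return float(min(max(x, lo), hi))


def _avn_class_fractions(config: StudyConfig, age: float) -> dict[str, tuple[float, float, float]]:
    """Cephalic/nodal/caudal trichrome fractions for one AVN heart.

    The nodal red fraction follows the age model red% = a + b*age (b
    negative: myocardial overlay thins with age); the cephalic band is
    richer and the caudal band poorer in myocardium, mirroring the
    decrease of red percentage from cephalic to caudal surface regions.
    The blue/white remainder splits 3:1 (collagen-dominant).
    """
    nodal = _clip01((config.red_a_pct + config.red_slope_pct_per_month * age) / 100.0)
    out = {}
    for region, offset in (
        ("cephalic", config.red_cephalic_offset),
        ("nodal", 0.0),
        ("caudal", config.red_caudal_offset),
    ):
        r = _clip01(nodal + offset)
        out[region] = (r, 0.75 * (1 - r), 0.25 * (1 - r))
    return out


@dataclass
class _SimulatedHeart:
    directory: str
    node_type: str
    age_months: float
    true_min_depths_um: list[float]


def simulate_study(config: StudyConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Generate and persist a phantom study under ``out_dir``.

    One dataset per (heart, node region); with ``node_type="both"`` each
    heart contributes an AVN and an SAN stack sharing its age. Writes
    per-section TIFF/PNG files, JSON sidecars, a ground-truth CSV and
    the config actually used.
    """
    out_dir = Path(out_dir)
    study_json = out_dir / _STUDY_JSON
    if study_json.exists() and not force:
        raise FileExistsError(f"{study_json} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)

    ages = np.geomspace(config.age_min_months, config.age_max_months, config.n_hearts)
    node_types = ["AVN", "SAN"] if config.node_type == "both" else [config.node_type]

    master = np.random.SeedSequence(config.seed)
    noise_rng = np.random.default_rng(master.spawn(1)[0])
    spec_seeds = iter(master.generate_state(2 * config.n_hearts * len(node_types)))

    hearts: list[_SimulatedHeart] = []
    truth_rows = []
    px = config.pixel_size_um
    width_um = (config.image_width_px - 1) * px
    cx = width_um / 2.0

    for h, age in enumerate(ages):
        heart_id = f"H{h + 1:02d}"
        for node_type in node_types:
            if node_type == "AVN":
                n_sec = config.avn_sections
                radius = config.avn_node_radius_um
                heart_min = (
                    config.depth_a_um
                    + config.depth_b_um * np.log(age)
                    + noise_rng.normal(0.0, config.depth_noise_sd_um)
                )
                heart_min = max(heart_min, config.depth_min_clip_um)
                labels = _avn_region_labels(n_sec)
                i_min = labels.index("transition") - 1  # last compact section
                origin = labels.index("transition")
                depth_curve = lambda i, m=heart_min, i0=i_min: m + config.v_slope_um_per_section * abs(i - i0)
                fractions = _avn_class_fractions(config, age)
                boundaries = (cx - 2 * radius, cx + 2 * radius)
            else:
                n_sec = config.san_sections
                radius = config.san_node_radius_um
                heart_min = float(
                    np.clip(
                        noise_rng.normal(config.san_depth_mean_um, config.san_depth_sd_um),
                        config.depth_min_clip_um,
                        config.san_depth_max_um,
                    )
                )
                labels = ["san_nodal"] * n_sec
                origin = None
                depth_curve = lambda i, m=heart_min: m
                white = config.san_white_frac
                fractions = {"all": (1 - white - 0.12, 0.12, white)}
                boundaries = None

            base_spec = SectionPhantomSpec(
                image_height_px=config.image_height_px,
                image_width_px=config.image_width_px,
                pixel_size_um=px,
                surface_shape=SineSurface(
                    base_row_um=config.surface_base_row_um,
                    amplitude_um=config.surface_amplitude_um,
                    period_um=config.surface_period_um,
                ),
                node_center_depth_um=radius,  # replaced per section
                node_radius_um=radius,
                class_fractions=fractions,
                region_boundaries_um=boundaries,
                noise_sd=config.phantom_noise_sd,
                seed=int(next(spec_seeds)),
                node_type=node_type,
            )
            series = make_heart_series(
                n_sec, config.section_interval_um, depth_curve, labels, base_spec
            )
            dataset = heart_dataset_from_series(
                series,
                heart_id=heart_id,
                age_months=float(age),
                node_type=node_type,
                section_interval_um=config.section_interval_um,
                alignment_origin_index=origin,
            )
            dirname = f"{heart_id}_{node_type}"
            write_heart(dataset, out_dir / dirname, force=force)
            hearts.append(
                _SimulatedHeart(
                    directory=dirname,
                    node_type=node_type,
                    age_months=float(age),
                    true_min_depths_um=[gt.true_min_depth_um for _, _, gt in series],
                )
            )
            for i, (_, _, gt) in enumerate(series):
                truth_rows.append(
                    {
                        "heart_id": heart_id,
                        "node_type": node_type,
                        "age_months": float(age),
                        "section_index": i,
                        "region": labels[i],
                        "true_min_depth_um": gt.true_min_depth_um,
                    }
                )

    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.10g")
    save_config(config, out_dir / "config.yaml")
    study_json.write_text(
        json.dumps(
            {
                "hearts": [h.directory for h in hearts],
                "config": config.to_dict(),
                "nodalmorph_version": __version__,
            },
            indent=1,
            sort_keys=True,
        )
    )
    logger.info("simulated %d datasets into %s", len(hearts), out_dir)
    return out_dir


def load_study(study_dir: str | Path) -> tuple[StudyConfig, list[HeartDataset]]:
    study_dir = Path(study_dir)
    meta = json.loads((study_dir / _STUDY_JSON).read_text())
    config = StudyConfig.from_dict(meta["config"])
    datasets = [load_heart(study_dir / name) for name in meta["hearts"]]
    return config, datasets


@dataclass
class StudyResults:
    depth: pd.DataFrame
    aligned_topology: pd.DataFrame
    coverage: pd.DataFrame
    stats: pd.DataFrame
    exclusions: pd.DataFrame
    report_text: str
    comparisons: dict = field(default_factory=dict)


def _measure_dataset(dataset: HeartDataset, config: StudyConfig):
    """Per-section depth + coverage measurements for one dataset."""
    depth_rows, coverage_rows, exclusion_rows = [], [], []
    min_depths = []
    radius_um, spacing_um = config.roi_geometry(dataset.node_type)
    for img, masks in dataset.sections:
        if masks.node_absent:
            exclusion_rows.append(
                {
                    "heart_id": dataset.heart_id,
                    "node_type": dataset.node_type,
                    "section_index": img.section_index,
                    "reason": "node_absent",
                }
            )
            min_depths.append(np.nan)
            continue
        profile, curve = measure_section_depth(
            masks,
            img.pixel_size_um,
            section_index=img.section_index,
            smoothing_param=config.smoothing_param(),
            sample_spacing_um=config.depth_spacing(),
        )
        i0, i1 = profile.projection_interval
        stats = section_depth_stats(profile.depth_um[i0 : i1 + 1])
        min_depths.append(profile.min_depth_um)
        depth_rows.append(
            {
                "heart_id": dataset.heart_id,
                "node_type": dataset.node_type,
                "age_months": dataset.age_months,
                "section_index": img.section_index,
                "axial_position_um": img.axial_position_um,
                "region": masks.region_label,
                "min_depth_um": profile.min_depth_um,
                "min_depth_whole_surface_um": profile.min_depth_whole_surface_um,
                "mean_depth_um": stats.mean,
                "median_depth_um": stats.median,
                "q1_depth_um": stats.q1,
                "q3_depth_um": stats.q3,
                "n_depth_samples": stats.n,
            }
        )

        # coverage on the same fitted surface
        class_map = (
            classify_red_dual(img.pixels, config.t_dominance, config.t_intensity)
            if dataset.node_type == "AVN"
            else classify_white(img.pixels, config.t_bright, config.t_spread)
        )
        surf_dmap = compute_distance_map(masks.surface_mask, img.pixel_size_um, source="surface")
        rois = place_rois(curve, radius_um, spacing_um)
        rois = roi_class_percentages(
            class_map,
            rois,
            masks.node_mask,
            masks.tissue_mask,
            surf_dmap,
            img.pixel_size_um,
            rule=config.superficial_rule,
        )
        partition_surface_regions(rois, profile.projection_arc_um)
        pct_col = "red_pct" if class_map.class_kind == "red" else "white_pct"
        for k in range(len(rois)):
            row = {
                "heart_id": dataset.heart_id,
                "node_type": dataset.node_type,
                "age_months": dataset.age_months,
                "section_index": img.section_index,
                "roi_index": k,
                "arc_position_um": rois.arc_positions_um[k],
                "region": rois.region[k],
                "class_kind": class_map.class_kind,
                "red_pct": np.nan,
                "white_pct": np.nan,
                "valid": bool(rois.valid[k]),
            }
            row[pct_col] = rois.percent[k]
            coverage_rows.append(row)
    return depth_rows, coverage_rows, exclusion_rows, min_depths


def _depth_regressions(depth: pd.DataFrame, config: StudyConfig) -> list[dict]:
    """The configured depth-age regression analyses (both variants)."""
    analyses = []
    avn = depth[depth.node_type == "AVN"]
    san = depth[depth.node_type == "SAN"]
    specs = []
    if len(avn):
        specs.append(("avn_overall_depth", avn, "log"))
        for region in ("extension", "compact", "transition"):
            sub = avn[avn.region == region]
            if len(sub):
                specs.append((f"avn_{region}_depth", sub, "log"))
    if len(san):
        specs.append(("san_depth", san, "log"))
        specs.append(("san_depth_linear", san, "linear"))
    for name, sub, kind in specs:
        for variant in config.regression_variants:
            if variant == "per_heart":
                g = sub.groupby("heart_id").agg(
                    age_months=("age_months", "first"), y=("min_depth_um", "min")
                )
                ages, ys = g.age_months.to_numpy(), g.y.to_numpy()
            else:
                ages, ys = sub.age_months.to_numpy(), sub.min_depth_um.to_numpy()
            if len(np.unique(ages)) < 3:
                continue
            res = fit_model(ages, ys, kind)
            analyses.append(_result_row(name, variant, res, "um"))
    return analyses


def _coverage_regressions(coverage: pd.DataFrame, config: StudyConfig) -> list[dict]:
    analyses = []
    cov = coverage[coverage.valid]
    for name, node_type, col in (
        ("avn_red_coverage", "AVN", "red_pct"),
        ("san_white_coverage", "SAN", "white_pct"),
    ):
        sub = cov[cov.node_type == node_type]
        if not len(sub):
            continue
        for variant in config.regression_variants:
            if variant == "per_heart":
                g = sub.groupby("heart_id").agg(
                    age_months=("age_months", "first"), y=(col, "mean")
                )
                ages, ys = g.age_months.to_numpy(), g.y.to_numpy()
            else:
                g = sub.groupby(["heart_id", "section_index"]).agg(
                    age_months=("age_months", "first"), y=(col, "mean")
                )
                ages, ys = g.age_months.to_numpy(), g.y.to_numpy()
            if len(np.unique(ages)) < 3:
                continue
            res = fit_model(ages, ys, "linear")
            analyses.append(_result_row(name, variant, res, "pct"))
    return analyses


def _result_row(name: str, variant: str, res, unit: str) -> dict:
    return {
        "analysis": name,
        "variant": variant,
        "model_kind": res.model_kind,
        "n": res.n,
        "a": res.a,
        "b": res.b,
        "b_magnitude": abs(res.b),
        "unit": unit,
        "r_squared": res.r_squared,
        "f_stat": res.f_stat,
        "p_value": res.p_value,
        "p_formatted": format_p(res.p_value),
    }


def _report_text(stats: pd.DataFrame, comparisons: dict, depth: pd.DataFrame, config: StudyConfig) -> str:
    lines = ["nodalmorph analysis report", "=" * 26, ""]
    for node_type in ("AVN", "SAN"):
        sub = depth[depth.node_type == node_type]
        if not len(sub):
            continue
        s = summarize(sub.min_depth_um)
        sd = f"{s.sd:.0f}" if s.sd is not None else "n/a"
        lines.append(
            f"{node_type} minimal depth: {s.mean:.0f}+/-{sd} um "
            f"(range {s.min:.0f} to {s.max:.0f} um, {s.n} sections)"
        )
    lines.append("")
    for _, row in stats.iterrows():
        lines += [
            f"== {row.analysis} [{row.model_kind}, {row.variant}] ==",
            f"n = {row.n}",
            f"a = {row.a:.3f} {row.unit}",
            f"b = {row.b:.3f} {row.unit}/{'month' if row.model_kind == 'linear' else 'log(month)'}"
            f"  (|b| = {row.b_magnitude:.3f})",
            f"R^2 = {row.r_squared:.3f}",
            f"F(1,{row.n - 2}) = {row.f_stat:.3f}, {row.p_formatted}",
            "",
        ]
    for name, comp in comparisons.items():
        lines.append(f"== {name} (one-way ANOVA + Tukey-Kramer) ==")
        for g in comp.labels:
            lines.append(f"{g}: {comp.means[g]:.1f}+/-{comp.sds[g]:.1f} (n={comp.ns[g]})")
        lines.append(f"ANOVA F = {comp.anova_f:.2f}, {format_p(comp.anova_p)}")
        for (g1, g2), p in sorted(comp.pairwise_p.items()):
            lines.append(f"{g1}:{g2} {format_p(p)}")
        lines.append("")
    return "\n".join(lines)


def run_study(
    study_dir: str | Path,
    out_dir: str | Path,
    config: StudyConfig | None = None,
    stages: tuple[str, ...] = ("depth", "coverage", "stats"),
    write_figures: bool = False,
) -> StudyResults:
    """Measure a study end to end and write the result tables.

    ``stages`` selects which tables are written; measurements are shared
    between stages. Returns the in-memory tables as well.
    """
    study_dir, out_dir = Path(study_dir), Path(out_dir)
    loaded_config, datasets = load_study(study_dir)
    if config is None:
        config = loaded_config

    depth_rows, coverage_rows, exclusion_rows = [], [], []
    min_depths, origins = {}, {}
    for ds in datasets:
        d, c, e, m = _measure_dataset(ds, config)
        depth_rows += d
        coverage_rows += c
        exclusion_rows += e
        if ds.node_type == "AVN" and ds.alignment_origin_index is not None:
            min_depths[ds.heart_id] = m
            origins[ds.heart_id] = ds.alignment_origin_index

    depth = pd.DataFrame(depth_rows)
    coverage = pd.DataFrame(coverage_rows)
    aligned = align_series(min_depths, origins, config.section_interval_um)
    exclusions = pd.DataFrame(
        exclusion_rows, columns=["heart_id", "node_type", "section_index", "reason"]
    )

    stats_rows, comparisons = [], {}
    if "stats" in stages:
        stats_rows += _depth_regressions(depth, config)
        stats_rows += _coverage_regressions(coverage, config)
        avn_cov = coverage[(coverage.node_type == "AVN") & coverage.valid]
        groups = {
            region: avn_cov[avn_cov.region == region].red_pct.to_numpy()
            for region in ("cephalic", "nodal", "caudal")
            if (avn_cov.region == region).sum() >= 2
        }
        if len(groups) >= 2:
            comparisons["avn_red_by_region"] = anova_tukey(groups)
    stats = pd.DataFrame(
        stats_rows,
        columns=[
            "analysis", "variant", "model_kind", "n", "a", "b", "b_magnitude",
            "unit", "r_squared", "f_stat", "p_value", "p_formatted",
        ],
    )

    tables = {"exclusions": exclusions}
    if "depth" in stages:
        tables["depth"] = depth
        tables["aligned_topology"] = aligned
    if "coverage" in stages:
        tables["coverage"] = coverage
    if "stats" in stages:
        tables["stats"] = stats
    write_results(tables, out_dir)

    report = _report_text(stats, comparisons, depth, config) if "stats" in stages else ""
    if report:
        (out_dir / "report.txt").write_text(report)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": config_hash,
                "seed": config.seed,
                "nodalmorph_version": __version__,
                "numpy_version": np.__version__,
                "stages": list(stages),
            },
            indent=1,
            sort_keys=True,
        )
    )
    if write_figures:
        make_figures(out_dir)
    return StudyResults(
        depth=depth,
        aligned_topology=aligned,
        coverage=coverage,
        stats=stats,
        exclusions=exclusions,
        report_text=report,
        comparisons=comparisons,
    )


def make_figures(out_dir: str | Path) -> list[Path]:
    """Advisory figures rebuilt from the emitted CSVs alone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []

    aligned_path = out_dir / "aligned_topology.csv"
    if aligned_path.exists():
        aligned = pd.read_csv(aligned_path)
        if len(aligned):
            fig, ax = plt.subplots(figsize=(6, 4))
            for heart_id, g in aligned.groupby("heart_id"):
                ax.plot(g.aligned_offset_um, g.min_depth_um, marker="o", label=heart_id)
            ax.set_xlabel("aligned offset (um)")
            ax.set_ylabel("minimal depth (um)")
            ax.legend(fontsize=6)
            fig.savefig(fig_dir / "aligned_topology.png", dpi=120)
            plt.close(fig)
            written.append(fig_dir / "aligned_topology.png")

    depth_path = out_dir / "depth.csv"
    if depth_path.exists():
        depth = pd.read_csv(depth_path)
        avn = depth[depth.node_type == "AVN"]
        if len(avn):
            g = avn.groupby("heart_id").agg(
                age_months=("age_months", "first"), y=("min_depth_um", "min")
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(g.age_months, g.y)
            ax.set_xlabel("postmenstrual age (months)")
            ax.set_ylabel("AVN minimal depth (um)")
            ax.set_xscale("log")
            fig.savefig(fig_dir / "avn_depth_vs_age.png", dpi=120)
            plt.close(fig)
            written.append(fig_dir / "avn_depth_vs_age.png")

    cov_path = out_dir / "coverage.csv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path)
        cov = cov[cov.valid]
        if len(cov):
            first = cov[
                (cov.heart_id == cov.heart_id.iloc[0])
                & (cov.section_index == cov.section_index.iloc[0])
            ]
            col = "red_pct" if first.class_kind.iloc[0] == "red" else "white_pct"
            fig, ax = plt.subplots(figsize=(6, 3))
            ax.plot(first.arc_position_um, first[col], marker=".")
            ax.set_xlabel("arc position (um)")
            ax.set_ylabel(f"trichrome {first.class_kind.iloc[0]} (%)")
            fig.savefig(fig_dir / "coverage_profile.png", dpi=120)
            plt.close(fig)
            written.append(fig_dir / "coverage_profile.png")
    return written


def contour_overlay_figure(
    study_dir: str | Path, out_path: str | Path, heart: str | None = None, section: int = 0
) -> Path:
    """Distance-map contour overlay for one section (line spacing per node type)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config, datasets = load_study(study_dir)
    ds = next(d for d in datasets if heart is None or d.heart_id == heart)
    img, masks = ds.sections[section]
    dmap = compute_distance_map(masks.node_mask, img.pixel_size_um, source="node")
    spacing = config.contour_spacing(ds.node_type)
    levels = np.arange(spacing, dmap.values_um.max(), spacing)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(img.pixels)
    if len(levels):
        ax.contour(dmap.values_um, levels=levels, colors="k", linewidths=0.5)
    ax.set_title(f"{ds.heart_id} {ds.node_type} section {section}")
    ax.axis("off")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
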
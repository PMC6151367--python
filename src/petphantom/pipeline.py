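"""End-to-end orchestration: cohort -> acquisitions -> masks -> features ->
statistical report, all reproducible from one master seed.

Every stage derives child seeds from the master seed with a counter-based
``numpy.random.SeedSequence`` scheme, so stages can be re-run independently
and two runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import (
    AcquisitionSettings,
    default_settings,
    make_test_retest,
    reconstruction_grid,
    simulate_acquisition,
)
from .evaluation import (
    build_report,
    cov_stability,
    friedman_stability,
    heterogeneity_discrimination,
    hgs_correlation,
    icc_reproducibility,
    sphericity_agreement,
)
from .radiomics import FEATURE_KEYS, extract_all
from .segmentation import (
    SegmentationMask,
    adaptive_threshold_segment,
    fixed_threshold_segment,
)
from .study import LesionRecord, build_cohort
from .volume import ActivityVolume, write_volume

log = logging.getLogger("petphantom")

_GT_COLUMNS = [
    "lesion_id", "shell_id", "v_gs_cc", "v_gs_active_cc", "s_gs",
    "cov_gs_pct", "gini_gs", "h_gs", "lb_gs", "layout", "seed",
]


@dataclass
class StudyConfig:
    """Everything needed to reproduce a full study run."""

    seed: int = 0
    n_lesions: int = 38
    gs_resolution_mm: float = 1.0
    segmentation_methods: tuple[str, ...] = ("adaptive", "fixed60")
    reconstruction_families: tuple[str, ...] = (
        "algorithm", "iterations", "subsets", "matrix", "fwhm"
    )
    n_test_retest_datasets: int = 2
    icc_form: str = "icc1"  # or "icc3"
    correlation: str = "spearman"  # or "pearson"
    save_volumes: bool = False
    save_masks: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("segmentation_methods", "reconstruction_families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["segmentation_methods"] = list(d["segmentation_methods"])
        d["reconstruction_families"] = list(d["reconstruction_families"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one run: enough to reproduce every output file."""

    config_hash: str
    package_version: str
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _child_seed(master: int, *tags: int) -> int:
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2**31))


def estimate_background(image: ActivityVolume) -> float:
    """Background estimate from the outer rind of the volume (the lesion sits
    centrally, so the border is background-dominated)."""
    rind = np.ones(image.shape, dtype=bool)
    rind[2:-2, 2:-2, 2:-2] = False
    return float(np.median(image.values[rind]))


def segment_volume(
    image: ActivityVolume, method: str, background: float | None = None
) -> SegmentationMask:
    if method == "fixed60":
        return fixed_threshold_segment(image)
    if method == "adaptive":
        bg = estimate_background(image) if background is None else background
        return adaptive_threshold_segment(image, background_estimate=bg)
    raise ValueError(f"unknown segmentation method {method!r}")


def _features_frame(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """lesions x features frame in registry order."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[list(FEATURE_KEYS)]


def ground_truth_frame(records: list[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "lesion_id": r.gt.lesion_id, "shell_id": r.gt.shell_id,
            "v_gs_cc": r.gt.v_gs, "v_gs_active_cc": r.gt.v_gs_active,
            "s_gs": r.gt.s_gs, "cov_gs_pct": r.gt.cov_gs,
            "gini_gs": r.gt.gini_gs, "h_gs": r.gt.h_gs, "lb_gs": r.gt.lb_gs,
            "layout": r.gt.layout, "seed": r.gt.seed,
        })
    return pd.DataFrame(rows, columns=_GT_COLUMNS)


def _simulate_and_extract(
    records: list[LesionRecord],
    settings: AcquisitionSettings,
    seed_tag: tuple[int, ...],
    master_seed: int,
    method: str = "adaptive",
    outdir: Path | None = None,
    volume_prefix: str = "",
) -> pd.DataFrame:
    rows = {}
    for i, rec in enumerate(records):
        s = replace(settings, seed=_child_seed(master_seed, *seed_tag, i))
        vol = simulate_acquisition(rec.phantom, s)
        if outdir is not None:
            write_volume(vol, outdir / f"{volume_prefix}{rec.lesion_id}.nii.gz")
        try:
            mask = segment_volume(vol, method)
        except Exception as exc:  # noqa: BLE001 - abort with context
            raise RuntimeError(
                f"stage simulate/segment failed at lesion {rec.lesion_id}: {exc}"
            ) from exc
        fv = extract_all(vol, mask.mask)
        rows[rec.lesion_id] = fv.values
    return _features_frame(rows)


def run_study(config: StudyConfig, outdir) -> RunManifest:
    """Execute the full study and write all tables under ``outdir``.

    Stages: cohort build -> standard acquisition + segmentation with every
    configured method -> feature extraction -> reconstruction-surrogate
    families -> test-retest datasets -> the statistical battery -> report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), package_version=__version__)
    master = config.seed
    config.to_yaml(outdir / "config.yaml")

    log.info("stage 1/6: building cohort of %d lesions", config.n_lesions)
    records = build_cohort(
        master, n_lesions=config.n_lesions, gs_resolution=config.gs_resolution_mm
    )
    gt = ground_truth_frame(records)
    gt.to_csv(outdir / "ground_truth.csv", index=False)
    manifest.outputs["ground_truth"] = "ground_truth.csv"

    std = default_settings()
    vol_dir = None
    if config.save_volumes:
        vol_dir = outdir / "volumes"
        vol_dir.mkdir(exist_ok=True)

    log.info("stage 2/6: standard acquisition, %d segmentation methods",
             len(config.segmentation_methods))
    features_by_method: dict[str, pd.DataFrame] = {}
    masks_by_lesion: dict[str, SegmentationMask] = {}
    for method in config.segmentation_methods:
        rows = {}
        for i, rec in enumerate(records):
            s = replace(std, seed=_child_seed(master, 1, i))  # same image per method
            vol = simulate_acquisition(rec.phantom, s)
            if vol_dir is not None and method == config.segmentation_methods[0]:
                write_volume(vol, vol_dir / f"{rec.lesion_id}.nii.gz")
            mask = segment_volume(vol, method)
            if method == "adaptive":
                masks_by_lesion[rec.lesion_id] = mask
            if config.save_masks:
                mdir = outdir / "masks" / method
                mdir.mkdir(parents=True, exist_ok=True)
                write_volume(
                    ActivityVolume(mask.mask.astype(float), vol.spacing, vol.origin),
                    mdir / f"{rec.lesion_id}.nii.gz",
                )
            rows[rec.lesion_id] = extract_all(vol, mask.mask).values
        df = _features_frame(rows)
        df.insert(0, "method", method)
        features_by_method[method] = df
    feat_all = pd.concat(features_by_method.values())
    feat_all.index.name = "lesion_id"
    feat_all.to_csv(outdir / "features.csv")
    manifest.outputs["features"] = "features.csv"

    log.info("stage 3/6: Friedman stability vs segmentation")
    fb = {m: df.drop(columns="method") for m, df in features_by_method.items()}
    if len(records) >= 5 and len(fb) >= 2:
        friedman_p = friedman_stability(fb)
    else:  # cohort below the test's minimum sample size
        friedman_p = pd.Series(np.nan, index=next(iter(fb.values())).columns,
                               name="friedman_p")

    log.info("stage 4/6: reconstruction families %s", config.reconstruction_families)
    grid = reconstruction_grid()
    fam_frames: dict[str, dict[str, pd.DataFrame]] = {}
    for fi, family in enumerate(config.reconstruction_families):
        fam_frames[family] = {}
        for si, setting in enumerate(grid[family]):
            fam_frames[family][setting.label] = _simulate_and_extract(
                records, setting, (2, fi, si), master
            )
    cov = cov_stability(fam_frames)

    log.info("stage 5/6: %d test-retest datasets", config.n_test_retest_datasets)
    tr_datasets = []
    for di in range(config.n_test_retest_datasets):
        test_rows, retest_rows = {}, {}
        for i, rec in enumerate(records):
            s = replace(std, seed=_child_seed(master, 3, di, i))
            v_test, v_retest = make_test_retest(rec.phantom, s)
            for vol, rows in ((v_test, test_rows), (v_retest, retest_rows)):
                mask = segment_volume(vol, "adaptive")
                rows[rec.lesion_id] = extract_all(vol, mask.mask).values
        tr_datasets.append((_features_frame(test_rows), _features_frame(retest_rows)))
    if len(records) >= 5:
        icc = icc_reproducibility(tr_datasets, form=config.icc_form)
    else:  # below the analysis' minimum pair count
        icc = pd.DataFrame(
            {f"icc_test{i+1}": np.nan for i in range(len(tr_datasets))},
            index=tr_datasets[0][0].columns,
        )
        icc["reproducible"] = False

    log.info("stage 6/6: significance tests and report")
    adaptive_feats = fb.get("adaptive", next(iter(fb.values())))
    hom_ids = gt.loc[gt.layout == "uniform", "lesion_id"]
    het_ids = gt.loc[gt.layout != "uniform", "lesion_id"]
    cols = adaptive_feats.columns
    if len(hom_ids) and len(het_ids):
        mw_p = heterogeneity_discrimination(
            adaptive_feats.loc[hom_ids], adaptive_feats.loc[het_ids]
        )
    else:  # cohort too small for group comparison
        mw_p = pd.Series(np.nan, index=cols, name="mw_p")
    if len(het_ids) >= 5:
        h_gs = gt.set_index("lesion_id").loc[het_ids, "h_gs"].to_numpy()
        hgs = hgs_correlation(adaptive_feats.loc[het_ids], h_gs,
                              method=config.correlation)
    else:
        hgs = pd.DataFrame(
            {"hgs_rho": np.nan, "hgs_corr_p": np.nan, "hgs_undefined": True},
            index=cols,
        )

    report = build_report(friedman_p, cov, icc, mw_p, hgs)

    # Sphericity vs ground truth, necrotic lesions excluded
    from .uptake import NECROTIC_LAYOUTS
    non_necro = gt.loc[~gt.layout.isin(NECROTIC_LAYOUTS), "lesion_id"]
    if len(non_necro) >= 3:
        spher_key = "IF_M:Sphericity"
        sp_p, sp_bias = sphericity_agreement(
            adaptive_feats.loc[non_necro, spher_key].to_numpy(),
            gt.set_index("lesion_id").loc[non_necro, "s_gs"].to_numpy(),
        )
        report.summary["sphericity_paired_t_p"] = sp_p
        report.summary["sphericity_mean_bias"] = sp_bias

    report.table.index.name = "feature"
    report.table.to_csv(outdir / "report.csv")
    (outdir / "summary.json").write_text(
        json.dumps(report.summary, indent=1, sort_keys=True)
    )
    manifest.outputs["report"] = "report.csv"
    manifest.outputs["summary"] = "summary.json"
    manifest.seeds = {"master": master, "scheme": "SeedSequence([master, stage, ...])"}
    manifest.to_json(outdir / "manifest.json")
    return manifest
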
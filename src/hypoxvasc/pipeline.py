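"""End-to-end pipeline: slides -> biomarkers -> cohort -> survival report.

A run is fully determined by (config, inputs): the YAML-serialisable
:class:`RunConfig` carries every module parameter plus one master seed, and
the manifest written at the end records the config hash, package versions
and all output files, so re-running the same config reproduces the same
CSV/JSON outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import hypoxvasc
from hypoxvasc import cohort as cohort_mod
from hypoxvasc import images, if_quant, mvd as mvd_mod, survival
from hypoxvasc.synthetic_cohort import CohortSimParams, generate_cohort
from hypoxvasc.synthetic_slides import SlideSimParams, generate_slide

DEFAULT_CANDIDATES = [
    "age",
    "biomarker_group",
    "grade_high",
    "histology_neec",
    "figo_advanced",
    "mi_deep",
    "lvsi_yes",
]
TABLE_VARS = [
    "grade",
    "histology",
    "figo_stage",
    "myometrial_invasion",
    "lvsi",
    "adjuvant",
    "recurrence",
]


@dataclass
class RunConfig:
    """Everything that determines a pipeline run."""

    seed: int = 0
    out_dir: str = "hypoxvasc_run"
    # slide inputs: list of {id, caix, vessel, mask, pixel_size} file entries,
    # or empty to simulate n_sim_slides synthetic slides instead
    slides: list[dict] = field(default_factory=list)
    n_sim_slides: int = 5
    slide_sim: dict = field(default_factory=dict)  # SlideSimParams overrides
    cohort_csv: str | None = None  # None -> simulate
    cohort_sim: dict = field(default_factory=dict)  # CohortSimParams overrides
    threshold_method: str = "otsu"
    caix_min_object_px: int = if_quant.CAIX_MIN_OBJECT_PX
    caix_cutoff: float = if_quant.CAIX_POSITIVITY_CUTOFF
    vessel_min_object_px: int = mvd_mod.VESSEL_MIN_OBJECT_PX
    field_area_mm2: float = mvd_mod.DEFAULT_FIELD_AREA_MM2
    n_hotspots: int = 3
    mvd_summary: str = "mean"
    mvd_stride: int | None = None
    connectivity: int = 2
    endpoints: list[str] = field(default_factory=lambda: ["DSS", "DFS", "DDFS"])
    screen_alpha: float = survival.SCREEN_ALPHA
    candidate_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _quantify_slide(
    caix_img: images.ChannelImage,
    vessel_img: images.ChannelImage,
    mask: images.RegionMask,
    cfg: RunConfig,
) -> dict:
    caix_res = if_quant.quantify_caix(
        caix_img,
        mask,
        threshold_method=cfg.threshold_method,
        min_object_px=cfg.caix_min_object_px,
        connectivity=cfg.connectivity,
    )
    vessel_thr = if_quant.determine_threshold(vessel_img, mask, cfg.threshold_method)
    vessel_bin = if_quant.segment_above(
        vessel_img, images.RegionMask(np.ones(vessel_img.shape, dtype=bool)), vessel_thr
    )
    mvd_res = mvd_mod.quantify_mvd(
        vessel_bin,
        mask,
        pixel_size_um=vessel_img.pixel_size,
        field_area_mm2=cfg.field_area_mm2,
        k=cfg.n_hotspots,
        summary=cfg.mvd_summary,
        min_object_px=cfg.vessel_min_object_px,
        connectivity=cfg.connectivity,
        stride=cfg.mvd_stride,
    )
    return {"caix": caix_res.to_dict(), "mvd": mvd_res.to_dict()}


def _load_or_simulate_slides(cfg: RunConfig) -> dict[str, dict]:
    quants: dict[str, dict] = {}
    if cfg.slides:
        for entry in cfg.slides:
            sid = entry.get("id", "?")
            try:
                for key in ("caix", "vessel", "mask"):
                    if not Path(entry[key]).exists():
                        raise FileNotFoundError(entry[key])
                px = float(entry.get("pixel_size", 2.0))
                caix_img = images.read_channel(entry["caix"], "hypoxia", px)
                vessel_img = images.read_channel(entry["vessel"], "vessel", px)
                mask = images.read_mask(entry["mask"])
                quants[sid] = _quantify_slide(caix_img, vessel_img, mask, cfg)
            except Exception as exc:
                raise RuntimeError(f"stage quantify failed for slide {sid!r}: {exc}") from exc
    else:
        child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_sim_slides)
        fractions = np.linspace(0.003, 0.2, cfg.n_sim_slides)
        for i in range(cfg.n_sim_slides):
            sid = f"SIM{i:03d}"
            params = SlideSimParams(
                **{
                    **dict(
                        true_caix_fraction=float(fractions[i]),
                        seed=int(child_seeds[i] % (2**31)),
                    ),
                    **cfg.slide_sim,
                }
            )
            try:
                _, caix_img, vessel_img, truth = generate_slide(params)
                quants[sid] = _quantify_slide(caix_img, vessel_img, truth.tumour_mask, cfg)
                quants[sid]["truth"] = truth.to_dict()
            except Exception as exc:
                raise RuntimeError(f"stage simulate/quantify failed for slide {sid!r}: {exc}") from exc
    return quants


def _load_or_simulate_cohort(cfg: RunConfig) -> pd.DataFrame:
    if cfg.cohort_csv is not None:
        path = Path(cfg.cohort_csv)
        if not path.exists():
            raise RuntimeError(f"stage cohort failed: missing cohort file {path}")
        return pd.read_csv(path)
    params = CohortSimParams(**{**{"seed": cfg.seed + 1}, **cfg.cohort_sim})
    return generate_cohort(params)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artefacts under cfg.out_dir.

    Returns the manifest (also written to manifest.json).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    quants = _load_or_simulate_slides(cfg)
    with open(out / "quantifications.json", "w") as fh:
        json.dump(quants, fh, indent=2, sort_keys=True)

    cohort = _load_or_simulate_cohort(cfg)
    cohort = cohort_mod.recode_lvsi(cohort)
    cohort = cohort_mod.derive_endpoints(cohort)
    cohort = cohort_mod.add_groups(cohort)
    cohort.to_csv(out / "cohort.csv", index=False)

    table_rows = []
    for var in TABLE_VARS:
        if var not in cohort.columns:
            continue
        ct = cohort_mod.crosstab(cohort, var, "biomarker_group")
        for level, row in ct.iterrows():
            table_rows.append({"variable": var, "level": level, **row.to_dict()})
    table1 = pd.DataFrame(table_rows)
    table1.to_csv(out / "descriptive_table.csv", index=False)

    analyses = {}
    surv_frames = []
    for ep in cfg.endpoints:
        tcol, ecol = survival.ENDPOINTS[ep]
        try:
            lr = survival.logrank_test(
                cohort[tcol], cohort[ecol], cohort["biomarker_group"]
            )
            lr_p = lr.p_value
        except ValueError:
            lr_p = None
        uni, multi = survival.screen_then_fit(
            cohort, ep, cfg.candidate_covariates, cfg.screen_alpha
        )
        frames = [r.to_frame() for r in uni]
        status = "ok"
        if multi is not None:
            frames.append(multi.to_frame())
        else:
            status = "no candidate passed the univariable screen"
        surv_frames.append(pd.concat(frames, ignore_index=True))
        analyses[ep] = {
            "logrank_p": lr_p,
            "multivariable_status": status,
            "n_events": uni[0].n_events,
        }
        if cfg.make_plots:
            _km_plot(cohort, tcol, ecol, ep, out / f"km_{ep.lower()}.png")
    pd.concat(surv_frames, ignore_index=True).to_csv(out / "survival_models.csv", index=False)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "hypoxvasc": hypoxvasc.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_slides": len(quants),
        "slide_ids": sorted(quants),
        "n_patients": int(len(cohort)),
        "endpoints": {k: v for k, v in analyses.items()},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _km_plot(cohort: pd.DataFrame, tcol: str, ecol: str, endpoint: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = survival.km_fit(cohort[tcol], cohort[ecol], cohort["biomarker_group"])
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.step(c.times, c.survival, where="post", label=f"{c.group} (n={int(c.at_risk[0])})")
    ax.set_xlabel("months")
    ax.set_ylabel(f"{endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(manifest: dict, out_dir: str | Path) -> Path:
    """Write a plain-text run report summarising the manifest."""
    if not manifest.get("n_patients"):
        raise ValueError("empty cohort: nothing to report")
    out = Path(out_dir)
    lines = [
        "hypoxvasc run report",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        f"slides quantified: {manifest['n_slides']}",
        f"patients: {manifest['n_patients']}",
        "",
        "endpoint analyses:",
    ]
    for ep, info in manifest["endpoints"].items():
        lr = info["logrank_p"]
        lr_txt = survival.format_p(lr) if lr is not None else "undefined"
        lines.append(
            f"  {ep}: log-rank p = {lr_txt}; events = {info['n_events']}; "
            f"multivariable: {info['multivariable_status']}"
        )
    lines.append("")
    lines.append("artefacts: " + ", ".join(manifest["outputs"]))
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
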
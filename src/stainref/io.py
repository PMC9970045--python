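"""Manifests, image I/O, run configuration, and the staged pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convergence import (
    build_pair_pool,
    compare_stain_curves,
    fit_power_law,
    pareto_optimal_size,
    sweep,
)
from .errors import DataError, SchemaError, StainRefError
from .evaluation import ConvergenceReport, convergence_experiment
from .histograms import (
    DEFAULT_C,
    DEFAULT_M_MAX,
    build_density_histogram,
    build_reference,
    cohort_bin_spec,
)
from .normalize import STAINS, normalize_image, extract_labic
from .stainsep import (
    DEFAULT_BETA,
    DEFAULT_LAMBDA,
    fit_stain_model,
    rgb_to_od,
    tissue_mask,
)

__all__ = [
    "CohortManifest",
    "read_manifest",
    "read_image",
    "write_image",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("stainref.io")


@dataclass
class CohortManifest:
    """Validated cohort listing: unique image ids and existing paths."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def image_ids(self) -> list[str]:
        return list(self.rows["image_id"])

    def path(self, image_id: str) -> Path:
        sel = self.rows.loc[self.rows["image_id"] == image_id, "path"]
        if sel.empty:
            raise DataError(f"unknown image id {image_id!r}")
        return Path(sel.iloc[0])

    def iter_images(self):
        for _, row in self.rows.iterrows():
            yield row["image_id"], read_image(row["path"])


def read_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a manifest CSV (columns: image_id, path, ...)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    for col in ("image_id", "path"):
        if col not in df.columns:
            raise SchemaError(f"manifest missing required column {col!r}")
    dupes = df["image_id"][df["image_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"duplicate id: {dupes.iloc[0]!r}")
    missing = [p for p in df["path"] if not Path(p).exists()]
    if missing:
        raise DataError(f"manifest path does not exist: {missing[0]}")
    return CohortManifest(rows=df)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/TIFF; alpha is dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"image not found: {path}")
    img = iio.imread(path)
    if img.dtype != np.uint8:
        raise DataError(f"{path}: unsupported bit depth {img.dtype} (need 8-bit)")
    if img.ndim == 3 and img.shape[-1] == 4:
        warnings.warn(f"{path}: dropping alpha channel")
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise DataError(f"{path}: need a 3-channel RGB image")
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB image losslessly (PNG or uncompressed TIFF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img, np.uint8))


@dataclass
class RunConfig:
    """All knobs of the staged pipeline, with documented defaults."""

    manifest: str = ""
    out_dir: str = "stainref_out"
    beta: float = DEFAULT_BETA
    sparsity_lambda: float = DEFAULT_LAMBDA
    c_const: float = DEFAULT_C
    i0: float = 255.0
    od_ceiling: float = 3.0
    m_max: int = DEFAULT_M_MAX
    s_max: int = 200
    n_perms: int = 1000
    pareto_fraction: float = 0.8
    pareto_convention: str = "cumulative_80"
    subset_sizes: list[int] = field(default_factory=lambda: [1, 10, 50])
    eval_perms: int = 8
    seeds: dict = field(
        default_factory=lambda: {
            "separate": 0,
            "sweep": 1,
            "reference": 2,
            "evaluate": 3,
        }
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stamp(config: RunConfig, stage: str) -> dict:
    return {
        "config_hash": config.config_hash(),
        "stage_seed": config.seeds.get(stage),
        "version": __version__,
    }


def _dump_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def separate_cohort(manifest: CohortManifest, config: RunConfig, out_dir: Path):
    """Stage 1: per-image stain model fits; densities stored as little-endian
    float32 with a JSON sidecar."""
    fits = {}
    seeds = np.random.SeedSequence(config.seeds["separate"]).generate_state(
        len(manifest)
    )
    for (image_id, img), s in zip(manifest.iter_images(), seeds):
        od = rgb_to_od(img, i0=config.i0)
        mask = tissue_mask(od, beta=config.beta)
        fit = fit_stain_model(
            od, mask, sparsity_lambda=config.sparsity_lambda, seed=int(s)
        )
        fits[image_id] = fit
        bin_path = out_dir / "densities" / f"{image_id}.f32"
        bin_path.parent.mkdir(parents=True, exist_ok=True)
        fit.concentrations.h.astype("<f4").tofile(bin_path)
        _dump_json(
            {
                "image_id": image_id,
                "stain_matrix": fit.w.tolist(),
                "objective": fit.objective,
                "rank_collapsed": fit.rank_collapsed,
                "densities_file": bin_path.name,
                "densities_dtype": "<f4",
                "densities_shape": list(fit.concentrations.h.shape),
                **_stamp(config, "separate"),
            },
            out_dir / "densities" / f"{image_id}.json",
        )
    log.info("separate: fitted %d images", len(fits))
    return fits


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow: separate -> histograms -> sweep -> pareto
    -> reference (at the optimal size) -> normalize -> evaluate.

    Every artifact is stamped with the config hash, stage seed, and
    package version.  Returns a summary dict of headline numbers.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    stage = "separate"
    try:
        fits = separate_cohort(manifest, config, out_dir)

        stage = "histograms"
        ids = list(fits)
        edges = cohort_bin_spec(
            {
                stain: [fits[i].concentrations.h[k] for i in ids]
                for k, stain in enumerate(STAINS)
            },
            m_max=config.m_max,
        )
        hists = {
            stain: [
                build_density_histogram(
                    fits[i].concentrations.h[k],
                    edges[stain],
                    c_const=config.c_const,
                    stain=stain,
                )
                for i in ids
            ]
            for k, stain in enumerate(STAINS)
        }
        log.info("histograms: %s bins per stain",
                 {s: len(e) - 1 for s, e in edges.items()})

        stage = "sweep"
        pool = build_pair_pool(hists, ids)
        s_max = min(config.s_max, 200)
        results = sweep(pool, s_max, config.n_perms, config.seeds["sweep"])
        fits_pl = {
            s: fit_power_law(r.sizes, r.sd_per_size)
            for s, r in results.items()
        }
        r_he, p_he = compare_stain_curves(
            results["hematoxylin"].sd_per_size, results["eosin"].sd_per_size
        )
        _dump_json(
            {
                "sizes": results["hematoxylin"].sizes.tolist(),
                "sd_per_size": {
                    s: r.sd_per_size.tolist() for s, r in results.items()
                },
                "power_law": {
                    s: dataclasses.asdict(f) for s, f in fits_pl.items()
                },
                "pearson_r_he": r_he,
                "pearson_p_he": p_he,
                **_stamp(config, "sweep"),
            },
            out_dir / "sweep.json",
        )
        pd.DataFrame(
            {
                "size": results["hematoxylin"].sizes,
                **{f"sd_{s}": r.sd_per_size for s, r in results.items()},
            }
        ).to_csv(out_dir / "sweep.csv", index=False)
        log.info("sweep: slopes %s", {s: f.slope for s, f in fits_pl.items()})

        stage = "pareto"
        pareto = pareto_optimal_size(
            results["hematoxylin"].sd_per_size,
            results["hematoxylin"].sizes,
            fraction=config.pareto_fraction,
            convention=config.pareto_convention,
        )
        optimal = min(pareto.optimal_size, len(ids))
        _dump_json(
            {
                "optimal_size": pareto.optimal_size,
                "optimal_size_clamped": optimal,
                "convention": pareto.convention,
                "optima": pareto.optima,
                **_stamp(config, "pareto"),
            },
            out_dir / "pareto.json",
        )
        log.info("pareto: optimal subset size %d", optimal)

        stage = "reference"
        rng = np.random.default_rng(config.seeds["reference"])
        sel = rng.choice(len(ids), size=optimal, replace=False)
        ref = build_reference(
            [fits[ids[i]].w for i in sel],
            {stain: [hists[stain][i] for i in sel] for stain in STAINS},
            [ids[i] for i in sel],
        )
        ref_path = out_dir / "reference.json"
        ref_path.write_text(ref.to_json())
        log.info("reference: built from %d images", optimal)

        stage = "normalize"
        norm_dir = out_dir / "normalized"
        per_image = {}
        for image_id in ids:
            img = read_image(manifest.path(image_id))
            out = normalize_image(
                img,
                ref,
                beta=config.beta,
                sparsity_lambda=config.sparsity_lambda,
                stain_matrix=fits[image_id].w,
                i0=config.i0,
            )
            write_image(out, norm_dir / f"{image_id}.png")
            od = rgb_to_od(out, i0=config.i0)
            mask = tissue_mask(od, beta=config.beta)
            per_image[image_id] = extract_labic(out, mask)
        _dump_json(
            {"mean_labic": per_image, **_stamp(config, "normalize")},
            out_dir / "normalized.json",
        )
        log.info("normalize: wrote %d tiles", len(per_image))

        stage = "evaluate"
        sizes = [s for s in config.subset_sizes if s <= len(ids)]
        report = convergence_experiment(
            [(i, read_image(manifest.path(i))) for i in ids],
            sizes,
            config.eval_perms,
            config.seeds["evaluate"],
            beta=config.beta,
            sparsity_lambda=config.sparsity_lambda,
            c_const=config.c_const,
            m_max=config.m_max,
        )
        (out_dir / "report.json").write_text(report.to_json())
        _report_csv(report).to_csv(out_dir / "report.csv", index=False)
        log.info("evaluate: sizes %s done", sizes)
    except StainRefError:
        log.error("pipeline failed at stage %r", stage)
        raise

    return {
        "n_images": len(ids),
        "optimal_size": optimal,
        "power_law": {s: dataclasses.asdict(f) for s, f in fits_pl.items()},
        "pearson_r_he": r_he,
        "mean_cohort_sd": report.mean_cohort_sd(),
    }


def _report_csv(report: ConvergenceReport) -> pd.DataFrame:
    """Flat per-(size, permutation) table: SD, Levene p vs next size, range."""
    levene_p = {a: p for a, _b, _w, p in report.levene_vs_next}
    rows = []
    for size in report.subset_sizes:
        for p_idx, sd in enumerate(report.cohort_sd_per_perm[size]):
            rows.append(
                {
                    "size": size,
                    "permutation": p_idx,
                    "cohort_sd": sd,
                    "levene_p_vs_next": levene_p.get(size, np.nan),
                    "range": report.range_per_size[size],
                }
            )
    return pd.DataFrame(rows)
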
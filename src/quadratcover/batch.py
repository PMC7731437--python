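"""Batch processing of image directories and cover-vs-index validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from .classify import (
    EXPLORED_D_RANGE,
    EXPLORED_G_RANGE,
    ClassificationParams,
    classify_image,
    cover_csv_row,
    export_mask_png,
    write_cover_csv,
)
from .errors import QuadratCoverError, ValidationError
from .imaging import CropRect, preprocess_image, read_image
from .spectra import RegressionResult, Spectrum, cai, ndvi, validate_cover

logger = logging.getLogger("quadratcover")

__all__ = ["BatchConfig", "BatchSummary", "run_batch",
           "read_overrides", "run_validation"]

IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class BatchConfig:
    """Configuration of one batch classification run."""

    input_dir: Path
    output_csv: Path
    masks_dir: Path | None = None
    defaults: ClassificationParams = field(default_factory=ClassificationParams)
    overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    crop: CropRect | None = None


@dataclass
class BatchSummary:
    """Outcome of a batch run; failures never produce CSV rows."""

    n_processed: int
    n_failed: int
    failures: list[tuple[str, str]]
    output_csv: Path
    masks_dir: Path | None

    @property
    def ok(self) -> bool:
        return self.n_failed == 0

    def to_dict(self) -> dict:
        return {
            "n_processed": self.n_processed,
            "n_failed": self.n_failed,
            "failures": [{"image": f, "error": e} for f, e in self.failures],
            "output_csv": str(self.output_csv),
            "masks_dir": str(self.masks_dir) if self.masks_dir else None,
        }


def read_overrides(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a per-image override CSV (columns: filename, g1, g2, d).

    Blank cells inherit the batch defaults.
    """
    df = pd.read_csv(path)
    required = {"filename"}
    if not required <= set(df.columns):
        raise ValueError(f"override CSV must contain a 'filename' column, got {list(df.columns)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        entry = {}
        for key in ("g1", "g2", "d"):
            if key in df.columns and pd.notna(row[key]):
                entry[key] = float(row[key])
        out[str(row["filename"])] = entry
    return out


def _warn_unusual(params: ClassificationParams, image: str) -> None:
    lo, hi = EXPLORED_G_RANGE
    for name, g in (("g1", params.g1), ("g2", params.g2)):
        if not (lo <= g <= hi):
            logger.warning(
                "%s: %s = %g outside the commonly explored range [%g, %g]",
                image, name, g, lo, hi,
            )
    dlo, dhi = EXPLORED_D_RANGE
    if not (dlo <= params.d <= dhi):
        logger.warning(
            "%s: d = %g outside the commonly explored range [%g, %g]",
            image, params.d, dlo, dhi,
        )


def run_batch(config: BatchConfig) -> BatchSummary:
    """Classify every readable RGB image in a directory.

    Images are processed in lexicographic filename order; per-image
    overrides replace only the parameter fields they specify. A failing
    image is logged, skipped and reported in the summary — it never
    produces a partial CSV row.
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    files = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"no images found in {input_dir}")
    names = {p.name for p in files}
    unknown = set(config.overrides) - names
    if unknown:
        raise ValueError(
            f"override filenames not present in {input_dir}: {sorted(unknown)}"
        )
    if config.masks_dir is not None:
        Path(config.masks_dir).mkdir(parents=True, exist_ok=True)

    rows = []
    failures: list[tuple[str, str]] = []
    for path in files:
        params = config.defaults.replace(**config.overrides.get(path.name, {}))
        _warn_unusual(params, path.name)
        try:
            raw = read_image(path)
            img = preprocess_image(raw, crop=config.crop)
            masks, cover = classify_image(img, params)
        except (QuadratCoverError, ValueError) as exc:
            logger.warning("%s: failed (%s)", path.name, exc)
            failures.append((path.name, str(exc)))
            continue
        logger.info(
            "%s: g1=%g g2=%g d=%g gv=%.4f%% sdm=%.4f%%",
            path.name, params.g1, params.g2, params.d,
            cover.gv_cover, cover.sdm_cover,
        )
        rows.append(cover_csv_row(path.name, cover, params))
        if config.masks_dir is not None:
            export_mask_png(masks, Path(config.masks_dir) / f"{path.stem}_mask.png")
    write_cover_csv(rows, config.output_csv)
    return BatchSummary(
        n_processed=len(rows),
        n_failed=len(failures),
        failures=failures,
        output_csv=Path(config.output_csv),
        masks_dir=Path(config.masks_dir) if config.masks_dir else None,
    )


SPECTRUM_SUFFIXES = {".csv", ".txt", ".sig", ".asd"}


def run_validation(
    cover_csv: str | Path,
    spectra_dir: str | Path,
    index: str = "ndvi",
    litter_csv: str | Path | None = None,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Regress image-derived cover on a spectral index across quadrats.

    Spectra are joined to covers on the filename stem. With
    ``index="ndvi"`` the response is extracted GV cover; with
    ``index="cai"`` it is extracted SDM cover plus the observed litter
    cover (NPV), read from ``litter_csv`` (columns: image,
    litter_cover_pct) — SDM alone does not track CAI because litter also
    carries the cellulose absorption signal.

    Returns the regression summary and the per-quadrat (cover, index)
    table.
    """
    if index not in ("ndvi", "cai"):
        raise ValueError("index must be 'ndvi' or 'cai'")
    covers = pd.read_csv(cover_csv)
    covers["stem"] = covers["image"].map(lambda s: Path(str(s)).stem)

    spectra_dir = Path(spectra_dir)
    spec_paths = sorted(
        p for p in spectra_dir.iterdir()
        if p.is_file() and p.suffix.lower() in SPECTRUM_SUFFIXES
    )
    if not spec_paths:
        raise ValidationError(f"no spectra found in {spectra_dir}")
    spec_by_stem = {p.stem: p for p in spec_paths}

    if index == "cai":
        if litter_csv is None:
            raise ValidationError(
                "CAI validation needs observed litter cover (NPV = SDM + litter)"
            )
        litter = pd.read_csv(litter_csv)
        litter["stem"] = litter["image"].map(lambda s: Path(str(s)).stem)
        covers = covers.merge(
            litter[["stem", "litter_cover_pct"]], on="stem", how="inner"
        )

    records = []
    index_fn = ndvi if index == "ndvi" else cai
    for _, row in covers.iterrows():
        path = spec_by_stem.get(row["stem"])
        if path is None:
            continue
        value = index_fn(Spectrum.from_file(path))
        if index == "ndvi":
            cover = float(row["gv_cover_pct"])
        else:
            cover = float(row["sdm_cover_pct"]) + float(row["litter_cover_pct"])
        records.append({"quadrat": row["stem"], "cover_pct": cover, index: value})
    if not records:
        raise ValidationError(
            "no spectra matched the cover table on filename stems"
        )
    table = pd.DataFrame(records)
    if len(table) < 3:
        raise ValidationError(
            f"need at least 3 matched quadrats for regression, got {len(table)}"
        )
    result = validate_cover(table["cover_pct"].to_numpy(), table[index].to_numpy())
    return result, table
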
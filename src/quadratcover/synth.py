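"""Synthetic quadrat scenes and reflectance spectra with known ground truth.

Real mixed-grassland quadrats contain five ground-cover components: green
vegetation (GV), standing dead matter (SDM), litter, soil crust and bare
soil. The generator paints each pixel with the mean color of its component
plus per-channel Gaussian noise, with exact per-component pixel counts
(largest-remainder allocation), so every classification result can be
compared against an exact ground truth.

The default palette encodes the physical situation the classifier relies
on: the standing dead canopy is sunlit and bright in all three bands,
while litter, crust and soil sit in the shaded understory and are darker.
Litter is the darkest component in the green band and soil the darkest in
blue (tied with green vegetation, whose reflectance is low in both red
and blue), which makes the five classes separable by the default
thresholds (g1 = g2 = 60, d = 1) in the noise-free case. Scenario presets
deliberately break these conditions to reproduce the known failure modes:
bluish foliage, dense two-layer standing dead canopies, bright
undecomposed litter, light soil, white flowers and green moss.

Spectra are linear mixtures of three fixed synthetic endmembers (green
vegetation, non-photosynthetic vegetation, soil) sampled at 1 nm over
350–2500 nm. The endmembers are piecewise linear and exactly flat across
the 2030–2210 nm window, so CAI is exactly zero for GV and soil and
positive (via a Gaussian cellulose trough at 2100 nm) for NPV. These are caricatures for testing index arithmetic and regression
plumbing, not radiometrically realistic spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .imaging import RawImage
from .spectra import Spectrum

__all__ = [
    "DEFAULT_PALETTE",
    "DEFAULT_FRACTIONS",
    "DEFAULT_NOISE_STD",
    "SceneSpec",
    "SyntheticQuadrat",
    "scene_preset",
    "SCENE_PRESETS",
    "generate_quadrat",
    "save_quadrat",
    "gv_endmember",
    "npv_endmember",
    "soil_endmember",
    "generate_spectrum",
]

#: Mean RGB digital numbers per component (0–255).
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    "gv": (60.0, 180.0, 60.0),
    "sdm": (210.0, 160.0, 150.0),
    "litter": (140.0, 95.0, 75.0),
    "crust": (100.0, 100.0, 100.0),
    "soil": (150.0, 115.0, 60.0),
}

#: A typical mid-season mixed-grass composition.
DEFAULT_FRACTIONS: dict[str, float] = {
    "gv": 0.30,
    "sdm": 0.20,
    "litter": 0.15,
    "crust": 0.10,
    "soil": 0.25,
}

#: Per-channel Gaussian color noise (digital numbers).
DEFAULT_NOISE_STD = 8.0


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic quadrat scene.

    fractions:
        Component → target area fraction; must sum to 1. Realized pixel
        counts are exact by largest-remainder allocation.
    palette:
        Component → mean RGB (0–255). Must cover every fraction key.
    noise_std:
        Per-channel Gaussian noise, either one value for all components
        or a component → value map.
    gv_blueness:
        Shift added to the blue channel of GV pixels, shrinking the
        (G - B) contrast the g2 threshold relies on (pale bluish foliage
        such as sagebrush or western wheatgrass).
    sdm_strata:
        Optional ``(bright_fraction, dark_dimming)``: that fraction of SDM
        pixels keeps the palette color, the rest is multiplied by
        ``dark_dimming`` (< 1) to emulate the shaded lower canopy of a
        dense standing dead layer.
    arrangement:
        ``"scatter"`` (seeded random positions; the classifier is
        per-pixel, so this is the default) or ``"blocks"`` (contiguous
        row-major patches, convenient for visual inspection and for
        exercising crops).
    """

    width: int = 100
    height: int = 100
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    palette: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    noise_std: float | dict[str, float] = DEFAULT_NOISE_STD
    gv_blueness: float = 0.0
    sdm_strata: tuple[float, float] | None = None
    arrangement: str = "scatter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be at least 1 x 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        missing = set(self.fractions) - set(self.palette)
        if missing:
            raise ValueError(f"palette missing components: {sorted(missing)}")
        for comp, rgb in self.palette.items():
            if len(rgb) != 3 or any(not (0 <= c <= 255) for c in rgb):
                raise ValueError(f"palette mean for {comp!r} must be 3 values in [0, 255]")
        if self.arrangement not in ("scatter", "blocks"):
            raise ValueError("arrangement must be 'scatter' or 'blocks'")
        if self.sdm_strata is not None:
            bright, dim = self.sdm_strata
            if not (0 <= bright <= 1) or not (0 < dim <= 1):
                raise ValueError("sdm_strata must be (fraction in [0,1], dimming in (0,1])")

    def component_noise(self, comp: str) -> float:
        if isinstance(self.noise_std, dict):
            std = self.noise_std.get(comp, 0.0)
        else:
            std = self.noise_std
        if std < 0:
            raise ValueError("noise std must be >= 0")
        return float(std)


@dataclass(frozen=True)
class SyntheticQuadrat:
    """A generated scene: image, per-pixel labels and exact fractions."""

    image: RawImage
    labels: np.ndarray  # H x W int, index into `components`
    components: tuple[str, ...]
    true_fractions: dict[str, float]
    spec: SceneSpec

    def label_mask(self, component: str) -> np.ndarray:
        return self.labels == self.components.index(component)


def _allocate_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder allocation of `total` pixels to components."""
    comps = list(fractions)
    exact = np.array([fractions[c] * total for c in comps])
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    out = dict(zip(comps, counts.tolist()))
    for comp, cnt in out.items():
        if fractions[comp] > 0 and cnt == 0:
            raise ValueError(
                f"image too small: component {comp!r} with fraction "
                f"{fractions[comp]} receives no pixels"
            )
    return out


def generate_quadrat(spec: SceneSpec) -> SyntheticQuadrat:
    """Render a scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    total = spec.width * spec.height
    counts = _allocate_counts(spec.fractions, total)
    comps = tuple(counts)

    labels_flat = np.repeat(np.arange(len(comps)), [counts[c] for c in comps])
    if spec.arrangement == "scatter":
        labels_flat = rng.permutation(labels_flat)
    # "blocks": keep contiguous row-major runs → horizontal patches

    colors = np.empty((total, 3), dtype=np.float64)
    for i, comp in enumerate(comps):
        sel = labels_flat == i
        n = int(sel.sum())
        mean = np.array(spec.palette[comp], dtype=np.float64)
        base = np.tile(mean, (n, 1))
        if comp == "gv" and spec.gv_blueness:
            base[:, 2] += spec.gv_blueness
        if comp == "sdm" and spec.sdm_strata is not None:
            bright_frac, dimming = spec.sdm_strata
            n_bright = int(round(bright_frac * n))
            base[n_bright:] *= dimming
        std = spec.component_noise(comp)
        if std > 0:
            base += rng.normal(0.0, std, size=(n, 3))
        colors[sel] = base

    pixels = np.clip(np.round(colors), 0, 255).astype(np.uint8)
    image = RawImage(pixels=pixels.reshape(spec.height, spec.width, 3))
    labels = labels_flat.reshape(spec.height, spec.width)
    true_fractions = {c: counts[c] / total for c in comps}
    return SyntheticQuadrat(
        image=image,
        labels=labels,
        components=comps,
        true_fractions=true_fractions,
        spec=spec,
    )


def _preset_specs() -> dict[str, dict]:
    """Keyword overrides defining each scenario preset."""
    return {
        # defaults separate all classes at (60, 60, 1)
        "default": {},
        # pale bluish foliage: (G - B) contrast of GV shrinks below the
        # default g2 = 60 but stays above 32, so lowering g2 recovers it
        "bluish": {"gv_blueness": 86.0},
        # dense standing dead canopy with a shaded lower stratum that
        # only d < 1 captures
        "dense-sdm": {
            "fractions": {"gv": 0.05, "sdm": 0.60, "litter": 0.15, "crust": 0.10, "soil": 0.10},
            "sdm_strata": (0.5, 0.80),
        },
        # bright undecomposed litter confuses the SDM rule at d = 1;
        # raising d suppresses it
        "light-litter": {
            "fractions": {"gv": 0.15, "sdm": 0.20, "litter": 0.30, "crust": 0.10, "soil": 0.25},
            "palette": {**DEFAULT_PALETTE, "litter": (185.0, 150.0, 125.0)},
        },
        # light dry soil likewise confuses the SDM rule at d = 1
        "light-soil": {
            "fractions": {"gv": 0.10, "sdm": 0.15, "litter": 0.15, "crust": 0.10, "soil": 0.50},
            "palette": {**DEFAULT_PALETTE, "soil": (195.0, 170.0, 145.0)},
        },
        # white flowers are brighter than everything, so no d in the
        # practical range removes them from the SDM class
        "white-flowers": {
            "fractions": {"gv": 0.30, "sdm": 0.20, "litter": 0.13, "crust": 0.10,
                          "soil": 0.22, "flower": 0.05},
            "palette": {**DEFAULT_PALETTE, "flower": (245.0, 243.0, 235.0)},
        },
        # green moss: (G - R) sits between 40 and 60 while (G - B) is
        # large, so g1 = 60 excludes it but a lowered g1 admits it
        "green-moss": {
            "palette": {**DEFAULT_PALETTE, "crust": (90.0, 116.0, 78.0)},
            "fractions": {"gv": 0.25, "sdm": 0.15, "litter": 0.15, "crust": 0.30, "soil": 0.15},
        },
    }


SCENE_PRESETS = tuple(_preset_specs())


def scene_preset(name: str, **overrides) -> SceneSpec:
    """A ready-made :class:`SceneSpec` for one of the named scenarios.

    Additional keyword arguments override the preset's fields
    (``seed``, ``width`` ... ).
    """
    presets = _preset_specs()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    spec = SceneSpec(**presets[name])
    return replace(spec, **overrides) if overrides else spec


def save_quadrat(quadrat: SyntheticQuadrat, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write scene PNG, label-map PNG and a JSON sidecar with the truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    image_path = directory / f"{stem}.png"
    labels_path = directory / f"{stem}_labels.png"
    json_path = directory / f"{stem}.json"
    Image.fromarray(quadrat.image.pixels, mode="RGB").save(image_path)
    Image.fromarray(quadrat.labels.astype(np.uint8), mode="P").save(labels_path)
    spec = quadrat.spec
    sidecar = {
        "components": list(quadrat.components),
        "true_fractions": quadrat.true_fractions,
        "spec": {
            "width": spec.width,
            "height": spec.height,
            "fractions": spec.fractions,
            "palette": {k: list(v) for k, v in spec.palette.items()},
            "noise_std": spec.noise_std,
            "gv_blueness": spec.gv_blueness,
            "sdm_strata": list(spec.sdm_strata) if spec.sdm_strata else None,
            "arrangement": spec.arrangement,
            "seed": spec.seed,
        },
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": image_path, "labels": labels_path, "sidecar": json_path}


# ---------------------------------------------------------------------------
# Synthetic reflectance endmembers
# ---------------------------------------------------------------------------

WAVELENGTHS = np.arange(350.0, 2501.0)

# Node tables for piecewise-linear endmembers. All three are exactly FLAT
# across 2000–2300 nm: the CAI shoulders (2030, 2210 nm) sit asymmetrically
# around 2100 nm, so even a sloped linear segment would leave a residual
# CAI; a flat segment makes the CAI of GV and soil exactly zero. The NPV
# cellulose trough is added separately.
_GV_NODES = (
    (350, 0.04), (500, 0.05), (550, 0.09), (640, 0.05), (670, 0.05),
    (700, 0.15), (750, 0.45), (800, 0.50), (1300, 0.50), (1450, 0.33),
    (1650, 0.40), (1940, 0.18), (2000, 0.21), (2300, 0.21), (2500, 0.15),
)
_NPV_BASE_NODES = (
    (350, 0.10), (670, 0.30), (800, 0.35), (1300, 0.42), (1900, 0.38),
    (2000, 0.39), (2300, 0.39), (2500, 0.33),
)
_SOIL_NODES = (
    (350, 0.15), (670, 0.27), (800, 0.33), (1300, 0.40), (2000, 0.42),
    (2300, 0.42), (2500, 0.40),
)

#: Depth and width (nm) of the synthetic 2100 nm cellulose-lignin trough.
_CELLULOSE_DEPTH = 0.08
_CELLULOSE_WIDTH = 35.0


def _from_nodes(nodes) -> np.ndarray:
    xs, ys = zip(*nodes)
    return np.interp(WAVELENGTHS, xs, ys)


def gv_endmember() -> Spectrum:
    """Green vegetation: low red, sharp red edge, high NIR, no 2100 nm trough."""
    return Spectrum(WAVELENGTHS, _from_nodes(_GV_NODES), name="gv_endmember")


def npv_endmember() -> Spectrum:
    """Dry plant material: bright, with a Gaussian 2100 nm cellulose trough."""
    base = _from_nodes(_NPV_BASE_NODES)
    trough = _CELLULOSE_DEPTH * np.exp(
        -(((WAVELENGTHS - 2100.0) / _CELLULOSE_WIDTH) ** 2)
    )
    return Spectrum(WAVELENGTHS, base - trough, name="npv_endmember")


def soil_endmember() -> Spectrum:
    """Bare soil: gently sloped, flat around both index regions (NDVI = 0.1)."""
    return Spectrum(WAVELENGTHS, _from_nodes(_SOIL_NODES), name="soil_endmember")


def generate_spectrum(
    gv_fraction: float,
    npv_fraction: float,
    soil_fraction: float,
    seed: int = 0,
    noise_std: float = 0.002,
    name: str | None = None,
) -> Spectrum:
    """Linear three-endmember mixture with small seeded Gaussian noise.

    Fractions must be non-negative and sum to 1. Noise std must not
    exceed 0.002 reflectance units (the generator mimics a well-calibrated
    field spectroradiometer); reflectance is clipped to [0, 1].
    """
    fracs = np.array([gv_fraction, npv_fraction, soil_fraction], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    if not (0 <= noise_std <= 0.002):
        raise ValueError("noise_std must lie in [0, 0.002]")
    mix = (
        fracs[0] * gv_endmember().reflectance
        + fracs[1] * npv_endmember().reflectance
        + fracs[2] * soil_endmember().reflectance
    )
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        mix = mix + rng.normal(0.0, noise_std, size=mix.shape)
    return Spectrum(WAVELENGTHS, np.clip(mix, 0.0, 1.0), name=name)
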
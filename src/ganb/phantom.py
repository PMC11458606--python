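"""Synthetic coronary cross-section phantoms with ground-truth masks.

Each phantom is a square grayscale image of a single vessel seen in cross
section: a bright annular wall, a contrast-filled (bright) patent lumen,
an eccentric hypodense plaque crescent occluding a configurable fraction
of the lumen area, optional bright calcification speckles inside the
plaque, and Gaussian pixel noise.  Masks label every pixel as background,
wall, patent lumen, plaque, or calcification, so segmentation metrics have
an exact reference.

Patient-level features (stenosis fraction, number of diseased vessels,
positive remodeling, spotty calcification count, prior myocardial
infarction) feed a deterministic high-risk rule: a case is high-risk iff
stenosis >= 70%, or two or more vessels are diseased, or positive
remodeling co-occurs with spotty calcification, or there is a history of
infarction/recurrent angina.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "MASK_LABELS",
    "DEFAULT_INTENSITIES",
    "label_risk",
    "generate_phantom",
    "generate_cohort",
    "export_cohort",
]

MASK_LABELS = {"background": 0, "wall": 1, "lumen": 2, "plaque": 3, "calcification": 4}

DEFAULT_INTENSITIES = {
    "background": 0.10,
    "wall": 0.55,
    "lumen": 0.85,  # contrast-filled
    "plaque": 0.40,
    "calcification": 0.95,
}

# inner (lumen) radius as a fraction of the outer wall radius
_LUMEN_FRACTION = 0.65

_RISK_FIELDS = ("stenosis_fraction", "n_vessels_diseased", "positive_remodeling",
                "n_calc_spots", "prior_mi")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vessel cross-section."""

    image_size: int = 32
    stenosis_fraction: float = 0.0
    n_vessels_diseased: int = 1
    positive_remodeling: bool = False
    n_calc_spots: int = 0
    prior_mi: bool = False
    noise_sd: float = 0.02
    vessel_radius: float = 12.0
    seed: int = 0
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))

    def __post_init__(self):
        if not 0.0 <= self.stenosis_fraction <= 1.0:
            raise ValueError("stenosis_fraction must be in [0, 1]")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not self.vessel_radius < self.image_size / 2:
            raise ValueError("vessel_radius must be < image_size / 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_vessels_diseased < 0 or self.n_calc_spots < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PhantomSample:
    image: np.ndarray  # 2-D float in [0, 1]
    masks: np.ndarray  # 2-D int labels 0..4
    features: dict  # realized quantities measured from the masks
    label: str  # "high" | "low"
    spec: PhantomSpec


def label_risk(features) -> str:
    """Deterministic high/low risk rule over patient features.

    Accepts a mapping or any object exposing the five risk fields; raises
    a ValueError naming the first missing field.
    """
    get = features.get if isinstance(features, dict) else lambda k, d=None: getattr(features, k, d)
    vals = {}
    for name in _RISK_FIELDS:
        v = get(name, None)
        if v is None:
            raise ValueError(f"missing risk feature: {name}")
        vals[name] = v
    if not 0.0 <= vals["stenosis_fraction"] <= 1.0:
        raise ValueError("stenosis_fraction must be in [0, 1]")
    high = (
        vals["stenosis_fraction"] >= 0.70
        or vals["n_vessels_diseased"] >= 2
        or (vals["positive_remodeling"] and vals["n_calc_spots"] >= 1)
        or bool(vals["prior_mi"])
    )
    return "high" if high else "low"


def _segment_fraction(t: float) -> float:
    """Area fraction of the unit disk beyond a chord at signed distance t."""
    t = np.clip(t, -1.0, 1.0)
    theta = 2.0 * np.arccos(t)
    return (theta - np.sin(theta)) / (2.0 * np.pi)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; bit-identical for identical (spec, seed).

    The plaque is a circular segment of the lumen disk.  Its chord offset is
    found by bisection directly on the pixel-counted occluded fraction, so
    the measured stenosis tracks the requested one to within pixel
    quantization (well inside the 0.05 contract).
    """
    s = spec.image_size
    rng = np.random.default_rng(spec.seed)
    r_outer = spec.vessel_radius
    r_lumen = _LUMEN_FRACTION * r_outer
    if spec.stenosis_fraction > 0 and r_lumen < 2.0:
        raise ValueError(
            f"stenosis unattainable: lumen radius {r_lumen:.2f}px too small to carve a plaque")

    c = (s - 1) / 2.0
    rows, cols = np.mgrid[0:s, 0:s].astype(float)
    dy, dx = rows - c, cols - c
    dist = np.hypot(dy, dx)

    phi = rng.uniform(0.0, 2.0 * np.pi)  # plaque direction (eccentricity)
    # outward bulge of the wall on the plaque side when remodeling is present
    if spec.positive_remodeling:
        ang = np.arctan2(dy, dx)
        r_wall = r_outer * (1.0 + 0.15 * np.clip(np.cos(ang - phi), 0.0, None))
    else:
        r_wall = r_outer

    masks = np.zeros((s, s), dtype=np.int64)
    masks[dist <= r_wall] = MASK_LABELS["wall"]
    lumen = dist <= r_lumen
    masks[lumen] = MASK_LABELS["lumen"]
    n_lumen = int(lumen.sum())

    if spec.stenosis_fraction > 0 and n_lumen > 0:
        proj = (dx * np.cos(phi) + dy * np.sin(phi)) / r_lumen  # signed chord coordinate
        target = spec.stenosis_fraction

        def occluded(t: float) -> float:
            return (lumen & (proj >= t)).sum() / n_lumen

        lo, hi = -1.5, 1.5  # beyond [-1,1] so 0%/100% are reachable
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if occluded(mid) > target:
                lo = mid
            else:
                hi = mid
        # pick whichever bracket end lands closer to the target
        t = lo if abs(occluded(lo) - target) <= abs(occluded(hi) - target) else hi
        plaque = lumen & (proj >= t)
        masks[plaque] = MASK_LABELS["plaque"]
    else:
        plaque = np.zeros_like(lumen)

    # spotty calcifications: small bright speckles inside the plaque
    # (fall back to the wall ring if the plaque has no pixels)
    region = plaque if plaque.any() else (masks == MASK_LABELS["wall"])
    if spec.n_calc_spots > 0 and region.any():
        cand = np.flatnonzero(region)
        centers = rng.choice(cand, size=min(spec.n_calc_spots, cand.size), replace=False)
        for flat in centers:
            r0, c0 = divmod(int(flat), s)
            rr = slice(max(r0 - 1, 0), min(r0 + 2, s))
            cc = slice(max(c0 - 1, 0), min(c0 + 2, s))
            spot = np.zeros((s, s), bool)
            spot[rr, cc] = True
            masks[spot & region] = MASK_LABELS["calcification"]

    image = np.empty((s, s), dtype=float)
    for name, lab in MASK_LABELS.items():
        image[masks == lab] = spec.intensities[name]
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, size=(s, s)), 0.0, 1.0)

    n_pla = int((masks == MASK_LABELS["plaque"]).sum() + (masks == MASK_LABELS["calcification"]).sum())
    n_pat = int((masks == MASK_LABELS["lumen"]).sum())
    nominal = n_pla + n_pat
    measured_stenosis = n_pla / nominal if nominal else 0.0
    features = {
        "stenosis_fraction": measured_stenosis,
        "n_vessels_diseased": spec.n_vessels_diseased,
        "positive_remodeling": spec.positive_remodeling,
        "n_calc_spots": spec.n_calc_spots,
        "prior_mi": spec.prior_mi,
    }
    return PhantomSample(image=image, masks=masks, features=features,
                         label=label_risk(features), spec=spec)


def _draw_spec(base: PhantomSpec, high: bool, rng: np.random.Generator) -> PhantomSpec:
    """One random spec whose realized label is `high` by construction.

    High-risk cases are stenosis-driven (72-92% occlusion) and may carry
    additional qualifying findings; low-risk cases stay clearly below the
    70% threshold with no other criterion firing.
    """
    if high:
        kw = dict(stenosis_fraction=float(rng.uniform(0.75, 0.92)))
        u = rng.random()
        if u < 0.2:
            kw["n_vessels_diseased"] = int(rng.integers(2, 4))
        elif u < 0.4:
            kw["positive_remodeling"] = True
            kw["n_calc_spots"] = int(rng.integers(1, 4))
        elif u < 0.5:
            kw["prior_mi"] = True
    else:
        kw = dict(
            stenosis_fraction=float(rng.uniform(0.05, 0.62)),
            n_vessels_diseased=1,
            positive_remodeling=False,
            prior_mi=False,
            n_calc_spots=int(rng.integers(0, 3)) if rng.random() < 0.3 else 0,
        )
    return replace(base, seed=int(rng.integers(2**31)), **kw)


def generate_cohort(n: int, class_mix: float, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomSample]:
    """n phantoms with exactly round(n * class_mix) high-risk cases."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must be in [0, 1]")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    n_high = int(round(n * class_mix))
    flags = np.zeros(n, dtype=bool)
    flags[:n_high] = True
    rng.shuffle(flags)
    samples = []
    for high in flags:
        sample = generate_phantom(_draw_spec(base, bool(high), rng))
        # construction guarantees the rule fires as intended
        assert (sample.label == "high") == bool(high)
        samples.append(sample)
    return samples


def _spec_hash(spec: PhantomSpec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def export_cohort(samples: list[PhantomSample], directory: str | Path) -> dict:
    """Write images (16-bit gray PNG), masks (palette PNG + flat text array),
    a features/labels CSV, and a JSON manifest; returns the manifest."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    palette = np.zeros((256, 3), dtype=np.uint8)
    palette[:5] = [(0, 0, 0), (200, 120, 80), (80, 80, 220), (220, 200, 60), (255, 255, 255)]
    rows, files = [], []
    for i, smp in enumerate(samples):
        img_name, msk_name, arr_name = f"img_{i:04d}.png", f"mask_{i:04d}.png", f"mask_{i:04d}.txt"
        img16 = np.round(smp.image * 65535.0).astype(np.uint16)
        Image.fromarray(img16).save(out / img_name)
        pm = Image.fromarray(smp.masks.astype(np.uint8), mode="P")
        pm.putpalette(palette.ravel().tolist())
        pm.save(out / msk_name)
        np.savetxt(out / arr_name, smp.masks, fmt="%d")
        rows.append({"index": i, "image": img_name, "mask": msk_name,
                     "label": smp.label, "seed": smp.spec.seed, **smp.features})
        files.extend([img_name, msk_name, arr_name])
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    manifest = {
        "n": len(samples),
        "files": files,
        "features_csv": "features.csv",
        "seeds": [s.spec.seed for s in samples],
        "spec_hashes": [_spec_hash(s.spec) for s in samples],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_image_png(path: str | Path) -> np.ndarray:
    """Load a 16-bit grayscale PNG back onto the [0, 1] scale."""
    arr = np.asarray(Image.open(path), dtype=float)
    return arr / 65535.0
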
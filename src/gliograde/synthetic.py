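"""Synthetic H&E-like cohort generator with grade-dependent nuclear structure.

Generates tile images and Ki-67 counts for a three-grade glioma cohort
(WHO II / III / IV).  Grade dependence is planted through per-grade profiles:
nuclear density, nucleus size and its spread (pleomorphism), maximum
eccentricity, haematoxylin staining darkness (hyperchromasia), spatial
clustering, and the Ki-67 proliferative-index distribution.  Rendering uses a
Beer-Lambert absorbance model with the Ruifrok-Johnston H&E stain vectors, so
downstream stain deconvolution recovers the planted channels.

Every case carries a ground-truth nucleus list (centres, semi-axes,
orientations) so segmentation can be tested against a known answer.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.color import rgb_from_hed

from gliograde.errors import ConfigurationError

GRADES = ("II", "III", "IV")

#: unit optical-density vectors for haematoxylin and eosin (Ruifrok-Johnston)
HEMATOXYLIN_OD = rgb_from_hed[0]
EOSIN_OD = rgb_from_hed[1]

#: baseline eosin absorbance of the stromal background
_BACKGROUND_EOSIN = 0.25
#: absorbance amplitude corresponding to darkness 1.0
_DARKNESS_TO_OD = 2.0


@dataclass(frozen=True)
class GradeProfile:
    """Generative parameters for one tumor grade at the 512-px tile scale."""

    grade: str
    nuclei_per_tile_mean: float
    nucleus_radius_mean_px: float
    nucleus_radius_sd_px: float
    eccentricity_max: float       # in [0, 1)
    stain_darkness_mean: float    # in [0, 1]
    cluster_fraction: float       # in [0, 1]
    ki67_pi_mean_pct: float
    ki67_pi_sd_pct: float

    def validate(self) -> None:
        if self.grade not in GRADES:
            raise ConfigurationError(f"unknown grade {self.grade!r}; expected one of {GRADES}")
        if self.nuclei_per_tile_mean < 0:
            raise ConfigurationError("nuclei_per_tile_mean must be >= 0")
        if self.nucleus_radius_mean_px <= 0 or self.nucleus_radius_sd_px < 0:
            raise ConfigurationError("nucleus radius mean must be > 0 and SD >= 0")
        if not 0.0 <= self.eccentricity_max < 1.0:
            raise ConfigurationError("eccentricity_max must be in [0, 1)")
        for name in ("stain_darkness_mean", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.ki67_pi_sd_pct < 0:
            raise ConfigurationError("ki67_pi_sd_pct must be >= 0")
        if not 0.0 <= self.ki67_pi_mean_pct <= 100.0:
            raise ConfigurationError("ki67_pi_mean_pct must be in [0, 100]")


#: Default per-grade profiles.  Densities, sizes and shape spreads increase with
#: grade (cellularity, nuclear enlargement, pleomorphism); Ki-67 PI means/SDs
#: follow the published per-grade norms 3.0±2.1 / 11.8±3.4 / 15.8±7.4 %.
DEFAULT_PROFILES: dict[str, GradeProfile] = {
    "II": GradeProfile("II", 150, 6.0, 1.0, 0.30, 0.50, 0.10, 3.0, 2.1),
    "III": GradeProfile("III", 300, 7.0, 2.0, 0.60, 0.60, 0.30, 11.8, 3.4),
    "IV": GradeProfile("IV", 450, 8.0, 3.0, 0.80, 0.75, 0.50, 15.8, 7.4),
}


@dataclass
class SyntheticCase:
    """One simulated patient: image tile(s), true grade, Ki-67 counts."""

    case_id: str
    grade: str
    image: np.ndarray | None
    ki67_positive: int
    ki67_total: int
    provenance_seed: int
    ground_truth: list[dict] = field(default_factory=list)
    image_path: str | None = None

    def load_image(self) -> np.ndarray:
        if self.image is not None:
            return self.image
        if self.image_path is None:
            raise ValueError(f"case {self.case_id} has neither in-memory image nor path")
        return iio.imread(self.image_path)


@dataclass
class CohortConfig:
    """Cohort composition and rendering geometry.

    Defaults reproduce the study population: 146 cases split 49/45/52 across
    grades II/III/IV, one 512-px tile per case.
    """

    counts_by_grade: dict[str, int] = field(
        default_factory=lambda: {"II": 49, "III": 45, "IV": 52}
    )
    tile_size_px: int = 512
    tiles_per_side: int = 1
    profiles: dict[str, GradeProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    image_format: str = "png"

    def validate(self) -> None:
        for grade, n in self.counts_by_grade.items():
            if grade not in GRADES:
                raise ConfigurationError(f"unknown grade {grade!r} in counts_by_grade")
            if n < 0:
                raise ConfigurationError(f"negative case count for grade {grade}")
        if self.tile_size_px < 64:
            raise ConfigurationError("tile_size_px must be >= 64")
        if self.tiles_per_side < 1:
            raise ConfigurationError("tiles_per_side must be >= 1")
        if self.image_format not in ("png", "tiff"):
            raise ConfigurationError("image_format must be 'png' or 'tiff'")
        for grade, prof in self.profiles.items():
            prof.validate()
            if prof.grade != grade:
                raise ConfigurationError(f"profile keyed {grade!r} has grade {prof.grade!r}")


@dataclass
class CohortManifest:
    cases: list[SyntheticCase]
    counts_by_grade: dict[str, int]
    master_seed: int

    def __len__(self) -> int:
        return len(self.cases)


def _smooth_noise(shape, rng, sigma):
    noise = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(noise, sigma)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _place_centers(rng, n, size_px, margin, radii, cluster_fraction, min_sep_factor,
                   max_attempts=50):
    """Sample nucleus centres with a minimum-separation rule.

    A ``cluster_fraction`` of nuclei is placed around Gaussian cluster centres,
    the remainder uniformly.  Candidates closer than
    ``min_sep_factor * (r_i + r_j)`` to an accepted nucleus are resampled; with
    min_sep_factor < 1 a candidate is accepted anyway after ``max_attempts``
    (dense tumor tissue does overlap), with min_sep_factor >= 1 it is skipped so
    the tile stays strictly overlap-free.
    """
    n_clustered = int(round(cluster_fraction * n))
    n_centers = max(1, math.ceil(n_clustered / 25)) if n_clustered else 0
    centers = rng.uniform(margin, size_px - margin, size=(n_centers, 2)) if n_centers else None
    cluster_sd = size_px / 14.0

    placed: list[tuple[float, float]] = []
    placed_r: list[float] = []
    kept_idx: list[int] = []
    for i in range(n):
        r_i = radii[i]
        accepted = None
        for attempt in range(max_attempts):
            if i < n_clustered:
                c = centers[rng.integers(n_centers)]
                cand = rng.normal(c, cluster_sd)
                cand = np.clip(cand, margin, size_px - margin)
            else:
                cand = rng.uniform(margin, size_px - margin, size=2)
            ok = True
            for (pr, pc), r_j in zip(placed, placed_r):
                d = math.hypot(cand[0] - pr, cand[1] - pc)
                if d < min_sep_factor * (r_i + r_j):
                    ok = False
                    break
            if ok:
                accepted = cand
                break
        if accepted is None and min_sep_factor < 1.0:
            accepted = cand  # tolerate overlap in dense tiles
        if accepted is not None:
            placed.append((float(accepted[0]), float(accepted[1])))
            placed_r.append(r_i)
            kept_idx.append(i)
    return placed, kept_idx


def render_tile(profile: GradeProfile, size_px: int, seed: int | None = None,
                rng: np.random.Generator | None = None,
                min_sep_factor: float = 0.7) -> tuple[np.ndarray, list[dict]]:
    """Render one H&E-like tile; returns (8-bit RGB image, ground-truth list).

    Draws ``N ~ Poisson(nuclei_per_tile_mean)`` elliptical nuclei in
    haematoxylin blue-purple over an eosin-pink textured background, plus
    Gaussian pixel noise.  Each ground-truth entry records the centre,
    semi-axes, orientation and staining darkness of one *rendered* nucleus,
    so ``len(ground_truth)`` always equals the number of nuclei in the image.
    """
    if size_px < 64:
        raise ConfigurationError("size_px must be >= 64")
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    n = int(rng.poisson(profile.nuclei_per_tile_mean))

    # nucleus geometry: semi-axes a >= b with a*b = r^2 (area-preserving)
    radii = np.clip(
        rng.normal(profile.nucleus_radius_mean_px, profile.nucleus_radius_sd_px, size=n),
        2.0, None,
    )
    eccs = rng.uniform(0.0, profile.eccentricity_max, size=n)
    shape_factor = (1.0 - eccs**2) ** 0.25
    semi_major = radii / shape_factor
    semi_minor = radii * shape_factor
    orientations = rng.uniform(0.0, math.pi, size=n)
    darkness = np.clip(rng.normal(profile.stain_darkness_mean, 0.06, size=n), 0.05, 1.0)

    margin = float(semi_major.max()) + 2.0 if n else 0.0
    margin = min(margin, size_px / 2.0 - 1.0)
    placed, kept = _place_centers(rng, n, size_px, margin, radii,
                                  profile.cluster_fraction, min_sep_factor)

    h_map = np.zeros((size_px, size_px), dtype=np.float64)
    truth: list[dict] = []
    chroma = _smooth_noise((size_px, size_px), rng, sigma=1.5)  # chromatin texture
    for (row, col), i in zip(placed, kept):
        rr, cc = skdraw.ellipse(row, col, semi_minor[i], semi_major[i],
                                shape=h_map.shape, rotation=orientations[i])
        amp = darkness[i] * _DARKNESS_TO_OD * (1.0 + 0.12 * chroma[rr, cc])
        np.maximum.at(h_map, (rr, cc), np.clip(amp, 0.05, None))
        truth.append({
            "center_row": row,
            "center_col": col,
            "semi_major_px": float(semi_major[i]),
            "semi_minor_px": float(semi_minor[i]),
            "orientation_rad": float(orientations[i]),
            "darkness": float(darkness[i]),
        })

    e_map = _BACKGROUND_EOSIN * (1.0 + 0.25 * _smooth_noise((size_px, size_px), rng, sigma=8.0))
    e_map = np.clip(e_map, 0.0, None)

    od = h_map[..., None] * HEMATOXYLIN_OD + e_map[..., None] * EOSIN_OD
    rgb = 255.0 * np.power(10.0, -od)
    rgb += rng.normal(0.0, 2.0, size=rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), truth


def sample_ki67_counts(profile: GradeProfile, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> tuple[int, int]:
    """Sample one (positive, total) Ki-67 count pair for a case.

    ``total`` is uniform on [1000, 3000] (the counting protocol examines at
    least 1000 tumor cells); the proliferative index is drawn
    Normal(mean, SD) in percent, censored to [0, 100], and ``positive`` is
    Binomial(total, PI/100).
    """
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    total = int(rng.integers(1000, 3001))
    pi_pct = float(np.clip(rng.normal(profile.ki67_pi_mean_pct, profile.ki67_pi_sd_pct), 0.0, 100.0))
    positive = int(rng.binomial(total, pi_pct / 100.0))
    return positive, total


def generate_cohort(config: CohortConfig, master_seed: int,
                    out_dir: str | Path | None = None) -> CohortManifest:
    """Generate a full cohort; deterministic given ``master_seed``.

    Per-case seeds are ``master_seed + case_index`` with cases enumerated in
    grade order II, III, IV.  If ``out_dir`` is given, images are written as
    PNG/TIFF with a CSV manifest and per-case ground-truth JSON sidecars;
    otherwise images stay in memory on the returned cases.
    """
    config.validate()
    out_path = Path(out_dir) if out_dir is not None else None
    image_size = config.tile_size_px * config.tiles_per_side

    cases: list[SyntheticCase] = []
    case_index = 0
    for grade in GRADES:
        n_cases = config.counts_by_grade.get(grade, 0)
        profile = config.profiles[grade]
        for j in range(n_cases):
            seed = master_seed + case_index
            rng = np.random.default_rng(seed)
            case_id = f"case_{case_index:04d}_{grade}"

            # multi-tile slides are assembled from independently rendered tiles
            rows = []
            truth: list[dict] = []
            for tr in range(config.tiles_per_side):
                row_imgs = []
                for tc in range(config.tiles_per_side):
                    img, t = render_tile(profile, config.tile_size_px, rng=rng)
                    for rec in t:
                        rec["center_row"] += tr * config.tile_size_px
                        rec["center_col"] += tc * config.tile_size_px
                    truth.extend(t)
                    row_imgs.append(img)
                rows.append(np.concatenate(row_imgs, axis=1))
            image = np.concatenate(rows, axis=0)
            assert image.shape[0] == image.shape[1] == image_size

            positive, total = sample_ki67_counts(profile, rng=rng)
            case = SyntheticCase(case_id, grade, image, positive, total, seed, truth)

            if out_path is not None:
                out_path.mkdir(parents=True, exist_ok=True)
                ext = "png" if config.image_format == "png" else "tif"
                img_file = out_path / f"{case_id}.{ext}"
                iio.imwrite(img_file, image)
                with open(out_path / f"{case_id}.truth.json", "w") as fh:
                    json.dump(truth, fh)
                case.image_path = str(img_file)
            cases.append(case)
            case_index += 1

    counts = {g: sum(1 for c in cases if c.grade == g) for g in GRADES}
    manifest = CohortManifest(cases, counts, master_seed)
    if out_path is not None and cases:
        write_manifest_csv(manifest, out_path / "manifest.csv")
    return manifest


def write_manifest_csv(manifest: CohortManifest, path: str | Path) -> None:
    # image paths are written relative to the manifest so that two runs into
    # different directories produce byte-identical manifests
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "grade", "image_path", "ki67_positive", "ki67_total", "seed"])
        for c in manifest.cases:
            rel = Path(c.image_path).name if c.image_path else ""
            writer.writerow([c.case_id, c.grade, rel,
                             c.ki67_positive, c.ki67_total, c.provenance_seed])


def load_manifest_csv(path: str | Path) -> CohortManifest:
    """Read back a cohort manifest written by :func:`generate_cohort`."""
    cases = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            img = row["image_path"] or None
            if img and not Path(img).is_absolute():
                img = str(base / img)
            cases.append(SyntheticCase(
                case_id=row["case_id"], grade=row["grade"], image=None,
                ki67_positive=int(row["ki67_positive"]), ki67_total=int(row["ki67_total"]),
                provenance_seed=int(row["seed"]), image_path=img,
            ))
    counts = {g: sum(1 for c in cases if c.grade == g) for g in GRADES}
    seed = cases[0].provenance_seed if cases else 0
    return CohortManifest(cases, counts, seed)


def profile_table() -> list[dict]:
    """The default grade-profile table as plain dicts (for reports/docs)."""
    return [asdict(DEFAULT_PROFILES[g]) for g in GRADES]
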
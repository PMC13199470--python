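"""Synthetic high-content-screening data with known ground truth.

Real Cell Painting campaigns pair each compound with (a) a bioactivity
profile, (b) a chemical structure, and (c) replicate multi-channel microscopy
images.  This module emulates that stack end to end so the generative model
and every evaluation stage can be exercised without any external data:

* compounds belong to *chemical series* whose sizes follow a Zipf-like skew —
  a few large series and a long tail of singletons, which is what makes
  cluster-based "realistically novel" splits meaningful; same-series
  compounds share a fingerprint prototype (perturbed per compound) so
  Tanimoto clustering approximately recovers the series;
* every series is assigned a *mechanism* (mechanism-of-action class), and a
  mechanism typically spans several series — distinct scaffolds hitting the
  same biology.  A held-out series is therefore novel chemistry whose
  mechanism is still represented in training, which is exactly the
  extrapolation regime a profile-conditioned generator is supposed to handle;
* each mechanism has a bioactivity signature; a compound's profile is the
  signature plus i.i.d. Gaussian noise;
* each mechanism maps to a phenotype archetype (cell count, size, elongation,
  mitochondrial punctae, death) and fields of view are rendered as ellipse
  cells on three channels: cytoplasm (red), mitochondria (green), nucleus
  (blue).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .chem import CompoundRecord
from .profiles import BioactivityProfile

__all__ = [
    "Phenotype",
    "SyntheticCompound",
    "ARCHETYPES",
    "sample_library",
    "render_field",
    "make_dataset",
    "library_table",
]

CHANNELS = ("cytoplasm", "mitochondria", "nucleus")  # RGB order
REFERENCE_SIZE = 64  # phenotype geometry is stated at this canvas size

FP_WIDTH = 2048
FP_ON_BITS = 64
FP_KEEP_P = 0.95
FP_ADD_MEAN = 3.0
PROFILE_BASELINE = 4.5       # inactive pAC50 level
PROFILE_ACTIVE_MEAN = 7.5    # potent pAC50 level for signature assays
PROFILE_NOISE_SD = 0.3
N_SIGNATURE_ASSAYS = 3


@dataclass(frozen=True)
class Phenotype:
    """Ground-truth morphology parameters at the 64x64 reference canvas."""

    cell_count_mean: float
    cell_radius_mean: float
    elongation: float = 1.1
    punctae_density: float = 0.0
    death: bool = False

    def __post_init__(self) -> None:
        if self.cell_count_mean < 0:
            raise ValueError("cell_count_mean must be >= 0")
        if self.cell_radius_mean <= 0:
            raise ValueError("cell_radius_mean must be > 0")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


# mechanism -> phenotype archetypes, cycled over by mechanism index
ARCHETYPES: dict[str, Phenotype] = {
    "neutral": Phenotype(12, 5.0),
    "dense": Phenotype(22, 4.5),
    "sparse": Phenotype(5, 5.0),
    "large": Phenotype(8, 7.0),
    "elongated": Phenotype(10, 5.0, elongation=2.5),
    "punctate": Phenotype(12, 5.0, punctae_density=4.0),
    "toxic": Phenotype(12, 5.0, death=True),
    "small_dense": Phenotype(18, 3.5),
}


@dataclass
class SyntheticCompound:
    record: CompoundRecord
    series_id: int
    mechanism_id: int
    archetype: str
    true_phenotype: Phenotype
    profile: BioactivityProfile

    @property
    def compound_id(self) -> str:
        return self.record.compound_id


def _series_sizes(n_compounds: int, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """Zipf-skewed series sizes, each series >= 1, summing exactly."""
    sizes = np.ones(n_series, dtype=np.int64)
    remaining = n_compounds - n_series
    if remaining > 0:
        weights = 1.0 / np.arange(1, n_series + 1)
        extra = rng.multinomial(remaining, weights / weights.sum())
        sizes += extra
    return sizes


def sample_library(
    n_compounds: int,
    n_mechanisms: int,
    profile_width: int = 64,
    seed: int | None = None,
    n_series: int | None = None,
    fp_width: int = FP_WIDTH,
    profile_noise_sd: float = PROFILE_NOISE_SD,
    phenotype_jitter: float = 0.1,
) -> list[SyntheticCompound]:
    """Sample a compound library with clustered chemistry and known phenotypes.

    ``n_series`` controls the chemical cluster structure (default 3 per
    mechanism); series ``s`` carries mechanism ``s mod n_mechanisms``, so the
    large series jointly cover every mechanism and the small/singleton series
    that end up held out share their biology with training chemistry.
    ``profile_noise_sd`` is the standard deviation of the i.i.d. Gaussian
    noise added to each mechanism's bioactivity signature (pAC50 units);
    ``phenotype_jitter`` is the log-scale per-compound jitter on cell count
    and radius.  A seed is mandatory — the library must be reproducible.
    """
    if seed is None:
        raise ValueError("a seed is mandatory: the library must be reproducible")
    if n_mechanisms > n_compounds:
        raise ValueError("n_mechanisms must be <= n_compounds")
    if n_mechanisms < 1:
        raise ValueError("need at least one mechanism")
    if n_series is None:
        n_series = min(3 * n_mechanisms, n_compounds)
    if n_series < n_mechanisms or n_series > n_compounds:
        raise ValueError("need n_mechanisms <= n_series <= n_compounds")
    rng = np.random.default_rng(seed)

    sizes = _series_sizes(n_compounds, n_series, rng)
    archetype_names = list(ARCHETYPES)
    # archetypes cycle over mechanisms so every archetype is represented
    mech_arch = [archetype_names[k % len(archetype_names)] for k in range(n_mechanisms)]

    # profile signature per mechanism (shared by all its series)
    signatures = []
    n_sig = min(N_SIGNATURE_ASSAYS, profile_width)
    for _k in range(n_mechanisms):
        sig = np.full(profile_width, PROFILE_BASELINE)
        active = rng.choice(profile_width, size=n_sig, replace=False)
        sig[active] = rng.normal(PROFILE_ACTIVE_MEAN, 0.5, size=n_sig)
        signatures.append(sig)

    compounds: list[SyntheticCompound] = []
    idx = 0
    for s in range(n_series):
        k = s % n_mechanisms
        on = rng.choice(fp_width, size=FP_ON_BITS, replace=False)  # series prototype
        counts = rng.integers(1, 4, size=FP_ON_BITS)
        base = ARCHETYPES[mech_arch[k]]
        for _ in range(sizes[s]):
            cid = f"CPD-{idx:05d}"
            keep = rng.random(FP_ON_BITS) < FP_KEEP_P
            fp = np.zeros(fp_width, dtype=np.int64)
            fp[on[keep]] = counts[keep]
            n_add = rng.poisson(FP_ADD_MEAN)
            if n_add:
                fp[rng.choice(fp_width, size=n_add, replace=False)] = 1
            profile_values = signatures[k] + rng.normal(0, profile_noise_sd, profile_width)
            jc, jr = np.exp(rng.normal(0, phenotype_jitter, 2))
            pheno = replace(
                base,
                cell_count_mean=base.cell_count_mean * jc,
                cell_radius_mean=base.cell_radius_mean * jr,
            )
            compounds.append(
                SyntheticCompound(
                    record=CompoundRecord(compound_id=cid, fingerprint=fp),
                    series_id=s,
                    mechanism_id=k,
                    archetype=mech_arch[k],
                    true_phenotype=pheno,
                    profile=BioactivityProfile(cid, profile_values, width=profile_width),
                )
            )
            idx += 1
    return compounds


def render_field(
    phenotype: Phenotype,
    height: int,
    width: int,
    seed: int | None = None,
    noise_sigma: float = 0.02,
    reference_size: int | None = None,
) -> np.ndarray:
    """Render one field of view as an (H, W, 3) float image in [0, 1].

    Cells are ellipses: cytoplasm on the red channel, a concentric nucleus
    disk on the blue channel, a faint mitochondrial haze plus bright punctae
    on the green channel.  Dead/dying compounds give ~10x fewer, half-size
    cells plus debris speckle.  By default the phenotype's count and radius
    are taken as absolute for this canvas; with ``reference_size`` set (as
    the dataset builder does) the geometry is stated at that canvas and
    scaled here — count by area, radius by side length.
    """
    if seed is None:
        raise ValueError("a seed is mandatory: rendering must be reproducible")
    if height < 32 or width < 32:
        raise ValueError("canvas must be at least 32x32")
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width, 3))

    area_scale = (height * width) / reference_size**2 if reference_size else 1.0
    len_scale = min(height, width) / reference_size if reference_size else 1.0
    count_mean = phenotype.cell_count_mean * area_scale
    radius_mean = phenotype.cell_radius_mean * len_scale
    if phenotype.death:
        count_mean *= 0.1
        radius_mean *= 0.5

    n_cells = rng.poisson(count_mean)
    centers: list[tuple[float, float]] = []
    min_sep = 1.6 * radius_mean
    for _ in range(n_cells):
        for _attempt in range(8):
            r = rng.uniform(radius_mean, height - radius_mean) if height > 2 * radius_mean else rng.uniform(0, height)
            c = rng.uniform(radius_mean, width - radius_mean) if width > 2 * radius_mean else rng.uniform(0, width)
            if all((r - rr) ** 2 + (c - cc) ** 2 > min_sep**2 for rr, cc in centers):
                break
        centers.append((r, c))

    for r, c in centers:
        rad = radius_mean * np.exp(rng.normal(0, 0.1))
        theta = rng.uniform(0, np.pi)
        a = rad * np.sqrt(phenotype.elongation)
        b = rad / np.sqrt(phenotype.elongation)
        rr, cc = draw_ellipse(r, c, a, b, shape=(height, width), rotation=theta)
        img[rr, cc, 0] = np.maximum(img[rr, cc, 0], 0.55 + rng.normal(0, 0.03))
        img[rr, cc, 1] = np.maximum(img[rr, cc, 1], 0.15)
        nr, nc = draw_disk((r, c), max(1.5, 0.45 * rad), shape=(height, width))
        img[nr, nc, 2] = np.maximum(img[nr, nc, 2], 0.85)
        n_punctae = rng.poisson(phenotype.punctae_density)
        for _ in range(n_punctae):
            ang = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0, 0.7)
            pr = r + rho * a * np.cos(ang) * np.cos(theta) - rho * b * np.sin(ang) * np.sin(theta)
            pc = c + rho * a * np.cos(ang) * np.sin(theta) + rho * b * np.sin(ang) * np.cos(theta)
            sr, sc = draw_disk((pr, pc), max(1.0, rad / 6), shape=(height, width))
            img[sr, sc, 1] = np.maximum(img[sr, sc, 1], 0.9)

    if phenotype.death:
        n_debris = rng.poisson(20 * area_scale)
        for _ in range(n_debris):
            dr, dc = rng.uniform(0, height), rng.uniform(0, width)
            sr, sc = draw_disk((dr, dc), 1.0, shape=(height, width))
            ch = rng.integers(0, 3)
            img[sr, sc, ch] = np.maximum(img[sr, sc, ch], 0.3)

    img += rng.normal(0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _image_seed(base_seed: int, compound_index: int, image_index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, compound_index, image_index]).generate_state(1)[0]
    )


def make_dataset(
    library: list[SyntheticCompound],
    images_per_compound: int = 24,
    train_images: int = 12,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    image_size: int = 64,
    fmt: str = "png",
) -> pd.DataFrame:
    """Render replicate fields per compound and return/write the manifest.

    The manifest has one row per image: compound_id, image_path, role
    (``train_img`` for the first ``train_images`` replicates, ``reserve_img``
    for the rest).  With ``out_dir=None`` images stay in memory in an
    ``image`` column; otherwise they are written as 8-bit PNG or 16-bit TIFF
    and the manifest CSV is placed alongside.
    """
    if not library:
        raise ValueError("library is empty")
    if seed is None:
        raise ValueError("a seed is mandatory: the dataset must be reproducible")
    if train_images > images_per_compound:
        raise ValueError("train_images cannot exceed images_per_compound")
    from .io import write_image

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)

    rows = []
    for ci, comp in enumerate(library):
        for ii in range(images_per_compound):
            img = render_field(
                comp.true_phenotype, image_size, image_size,
                seed=_image_seed(seed, ci, ii), reference_size=REFERENCE_SIZE,
            )
            role = "train_img" if ii < train_images else "reserve_img"
            if out_dir is None:
                rows.append(
                    {"compound_id": comp.compound_id, "image_path": "", "role": role, "image": img}
                )
            else:
                rel = f"images/{comp.compound_id}_{ii:02d}.{fmt}"
                write_image(out_dir / rel, img, channels=CHANNELS)
                rows.append({"compound_id": comp.compound_id, "image_path": rel, "role": role})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def library_table(library: list[SyntheticCompound]) -> pd.DataFrame:
    """Ground-truth table: one row per compound with mechanism and phenotype."""
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in library],
            "series_id": [c.series_id for c in library],
            "mechanism_id": [c.mechanism_id for c in library],
            "archetype": [c.archetype for c in library],
            "cell_count_mean": [c.true_phenotype.cell_count_mean for c in library],
            "cell_radius_mean": [c.true_phenotype.cell_radius_mean for c in library],
            "elongation": [c.true_phenotype.elongation for c in library],
            "punctae_density": [c.true_phenotype.punctae_density for c in library],
            "death": [c.true_phenotype.death for c in library],
        }
    )
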
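"""Ground-truthed synthetic phase-contrast / nuclei image pairs.

The generator emulates the optical structure the counting method relies on:
nonoverlapping epithelial cells rendered as dark interior discs ringed by a
bright annular halo on a mid-grey background, plus spurious bright and dark
noise blobs, together with a paired epifluorescence channel containing one
bright nucleus disc strictly inside each cell body.  It makes no attempt to
simulate phase-contrast optics physically — only the contrast relations
(dark interior, bright edge) that the dual-filter segmentation exploits.

Ground truth records every placed object, so the full taxonomy of detection
outcomes (correct / merged / split / missed / noise) can be scored exactly.
All randomness is driven by a single integer seed, and generation is
bit-reproducible for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import GenerationError, ParameterError
from .image_io import DEFAULT_PIXEL_SIZE, Image8


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Defaults mirror the scale of H400 oral keratinocytes imaged with a x10
    objective: cell radius ~13 px (~10 um), a halo glow decaying over
    ~3 px, nuclei at half the cell radius, on an 800x600 px field.  The
    halo is rendered as an exponential glow on a random arc of the
    circumference (halos vanish where neighbouring cells touch), interiors
    shade from darkest centre toward the edge and carry band-limited
    cytoplasm texture, and each cell has a random overall contrast.
    """

    shape: tuple[int, int] = (600, 800)  # (rows, cols)
    n_cells: int = 50
    cell_radius_mean: float = 13.0
    cell_radius_sd: float = 1.5
    halo_width: float = 3.0
    halo_brightness: float = 60.0
    interior_darkness: float = 25.0
    interior_gradient: float = 0.5  # darkness fades toward the cell edge
    halo_coverage_range: tuple[float, float] = (0.5, 0.9)
    cell_contrast_range: tuple[float, float] = (0.5, 1.0)
    cell_texture_sd: float = 15.0
    cell_texture_scale: float = 2.5  # Gaussian correlation length, px
    background_level: float = 128.0
    background_noise_sd: float = 8.0
    psf_sigma: float = 1.0  # optical blur applied before sensor noise
    fluor_noise_sd: float = 0.0  # fluorescence channel is near-noiseless
    n_noise_blobs: int = 15
    noise_blob_area_range: tuple[int, int] = (20, 150)  # debris-sized
    nucleus_radius_fraction: float = 0.5
    min_center_spacing: float | None = None  # default: 2*(radius+halo) + 2
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_noise_blobs < 0:
            raise ParameterError("object counts must be non-negative")
        if self.cell_radius_mean <= 0:
            raise ParameterError("cell radius must be positive")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ParameterError("nucleus_radius_fraction must be in (0, 1)")
        if self.min_center_spacing is not None and self.min_center_spacing < 0:
            raise ParameterError("min_center_spacing must be >= 0")

    @property
    def spacing(self) -> float:
        # cell bodies stay disjoint but halos may touch, as in a monolayer
        if self.min_center_spacing is not None:
            return self.min_center_spacing
        return 2.0 * self.cell_radius_mean + 4.0


@dataclass
class GroundTruth:
    """Everything the generator placed in one scene."""

    centers: np.ndarray        # (n_cells, 2) float (row, col)
    radii: np.ndarray          # (n_cells,) float
    nucleus_labels: np.ndarray  # int raster, one positive label per nucleus
    noise_labels: np.ndarray    # int raster, one positive label per blob
    true_count: int

    @property
    def n_noise(self) -> int:
        return int(self.noise_labels.max())


def _place_centers(rng: np.random.Generator, shape, n: int, margin: float,
                   spacing: float, retry_cap: int = 2000) -> np.ndarray:
    """Sample non-overlapping centers.

    Sparse fields use uniform dart throwing (isolated colonies at random
    positions); dense fields switch to a jittered hexagonal lattice,
    which both matches the quasi-ordered packing of near-confluent
    epithelial sheets and stays feasible right up to the lattice capacity,
    where dart throwing jams long before.
    """
    h, w = shape
    if n == 0:
        return np.empty((0, 2))
    uh, uw = h - 2 * margin, w - 2 * margin
    if uh <= 0 or uw <= 0:
        raise GenerationError("field too small for the requested cell size")
    if spacing > 0 and n > 0.45 * (uh * uw) / spacing**2:
        return _jittered_lattice(rng, (uh, uw), margin, n, spacing)
    centers: list[np.ndarray] = []
    stack = np.empty((0, 2))
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > retry_cap * max(n, 1):
            raise GenerationError(
                f"could not place {n} objects with spacing {spacing:.1f} px; "
                "shrink the cells or the count")
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if not len(centers) or \
                np.hypot(*(stack - cand).T).min() >= spacing:
            centers.append(cand)
            stack = np.array(centers)
    return stack.reshape(n, 2)


def _jittered_lattice(rng: np.random.Generator, usable, margin: float,
                      n: int, spacing: float) -> np.ndarray:
    """n random sites of a jittered hexagonal lattice with min separation
    ``spacing``."""
    uh, uw = usable
    for jitter_frac in (0.25, 0.15, 0.08, 0.0):
        jitter = jitter_frac * spacing
        pitch = spacing + 2.0 * jitter
        row_step = pitch * np.sqrt(3.0) / 2.0
        rows = int(uh // row_step) + 1
        cols = int(uw // pitch) + 1
        sites = []
        for i in range(rows):
            offset = 0.5 * pitch if i % 2 else 0.0
            for j in range(cols):
                y = margin + i * row_step
                x = margin + offset + j * pitch
                if y <= margin + uh and x <= margin + uw:
                    sites.append((y, x))
        if len(sites) >= n:
            chosen = rng.choice(len(sites), size=n, replace=False)
            pts = np.asarray(sites)[chosen]
            return pts + rng.uniform(-jitter, jitter, (n, 2)) / np.sqrt(2.0)
    raise GenerationError(
        f"cannot fit {n} objects with spacing {spacing:.1f} px even on a "
        "hexagonal lattice; shrink the cells or the count")


def _patch(shape, center, radius: float):
    """Bounding-box slices and the distance map of a disc neighbourhood."""
    h, w = shape
    r0 = int(max(0, np.floor(center[0] - radius - 1)))
    r1 = int(min(h, np.ceil(center[0] + radius + 2)))
    c0 = int(max(0, np.floor(center[1] - radius - 1)))
    c1 = int(min(w, np.ceil(center[1] + radius + 2)))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - center[0], xx - center[1])
    return (slice(r0, r1), slice(c0, c1)), d, np.arctan2(yy - center[0],
                                                         xx - center[1])


def _paint_disc(canvas: np.ndarray, center, radius: float, value: float,
                inner: float = 0.0) -> None:
    """Add ``value`` on the annulus inner < d <= radius (disc if inner=0)."""
    box, d, _ = _patch(canvas.shape, center, radius)
    canvas[box][(d <= radius) & (d > inner)] += value


def _label_disc(canvas: np.ndarray, center, radius: float, label: int) -> None:
    box, d, _ = _patch(canvas.shape, center, radius)
    canvas[box][d <= radius] = label


def generate_scene(spec: SceneSpec) -> tuple[Image8, Image8, GroundTruth]:
    """Render one phase-contrast / fluorescence pair with ground truth.

    Returns ``(pc, fluor, truth)``.  The phase-contrast channel is the
    noisy background plus, per cell, a darkened interior disc and a raised
    halo annulus; noise blobs are small bright or dark spots away from the
    cells.  The fluorescence channel has a dark background and one bright
    disc per nucleus, strictly inside its cell.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    glow_extent = 3.0 * spec.halo_width  # glow truncated here
    margin = spec.cell_radius_mean + glow_extent + 2
    centers = _place_centers(rng, spec.shape, spec.n_cells, margin, spec.spacing)
    radii = np.clip(
        rng.normal(spec.cell_radius_mean, spec.cell_radius_sd, spec.n_cells),
        0.5 * spec.cell_radius_mean, 1.5 * spec.cell_radius_mean)

    pc = np.full((h, w), spec.background_level, dtype=np.float64)
    contrasts = rng.uniform(*spec.cell_contrast_range, spec.n_cells)
    coverages = rng.uniform(*spec.halo_coverage_range, spec.n_cells)
    arc_starts = rng.uniform(-np.pi, np.pi, spec.n_cells)
    for center, r, contrast, cov, a0 in zip(centers, radii, contrasts,
                                            coverages, arc_starts):
        box, d, ang = _patch((h, w), center, r + glow_extent)
        inside = d <= r
        # interior: darkest at the centre, fading toward the edge
        shading = 1.0 - spec.interior_gradient * (d / max(r, 1e-9)) ** 2
        pc[box][inside] -= (spec.interior_darkness * contrast
                            * shading[inside])
        # halo: exponential glow outside the body, on a random arc
        # (absent where neighbouring cells are in contact)
        arc = (ang - a0) % (2.0 * np.pi) <= cov * 2.0 * np.pi
        glow = (d > r) & (d <= r + glow_extent) & arc
        pc[box][glow] += (spec.halo_brightness * contrast
                          * np.exp(-(d[glow] - r) / max(spec.halo_width,
                                                        1e-9)))
    if spec.cell_texture_sd > 0 and spec.n_cells:
        # mottled cytoplasm: band-limited noise confined to cell interiors
        from scipy import ndimage as ndi

        texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)),
                                      spec.cell_texture_scale)
        texture *= spec.cell_texture_sd / texture.std()
        interior = np.zeros((h, w), dtype=bool)
        for center, r in zip(centers, radii):
            box, d, _ = _patch((h, w), center, r)
            interior[box] |= d <= r
        pc[interior] += texture[interior]
    # Noise blobs: small discs, half darkened and half brightened, kept
    # clear of the cells so ground truth stays unambiguous.
    noise_labels = np.zeros((h, w), dtype=np.int64)
    lo_a, hi_a = spec.noise_blob_area_range
    placed = 0
    attempts = 0
    blob_max_r = float(np.sqrt(hi_a / np.pi)) + 1.0
    while placed < spec.n_noise_blobs:
        attempts += 1
        if attempts > 5000 * max(spec.n_noise_blobs, 1):
            raise GenerationError("could not place noise blobs clear of cells")
        cand = np.array([rng.uniform(2, h - 2), rng.uniform(2, w - 2)])
        area = rng.uniform(lo_a, hi_a)
        br = float(np.sqrt(area / np.pi))
        clearance = (spec.cell_radius_mean * 1.5 + glow_extent
                     + blob_max_r + 2)
        if len(centers) and np.min(np.hypot(*(centers - cand).T)) < clearance:
            continue
        sign = -1.0 if placed % 2 == 0 else 1.0  # alternate dark / bright
        amp = spec.halo_brightness if sign > 0 else spec.interior_darkness
        _paint_disc(pc, cand, br, sign * amp)
        placed += 1
        _label_disc(noise_labels, cand, br, placed)

    if spec.psf_sigma > 0:
        from scipy import ndimage as ndi

        pc = ndi.gaussian_filter(pc, spec.psf_sigma)
    if spec.background_noise_sd > 0:
        pc += rng.normal(0.0, spec.background_noise_sd, (h, w))

    pc8 = Image8(np.clip(np.rint(pc), 0, 255).astype(np.uint8),
                 pixel_size=spec.pixel_size)

    fluor = np.full((h, w), 8.0)
    if spec.fluor_noise_sd > 0:
        fluor += rng.normal(0.0, spec.fluor_noise_sd, (h, w))
    nucleus_labels = np.zeros((h, w), dtype=np.int64)
    for i, (center, r) in enumerate(zip(centers, radii), start=1):
        nr = spec.nucleus_radius_fraction * r
        # jitter the nucleus inside the cell, keeping PP(N, C) true
        slack = max(r - nr - 1.0, 0.0)
        offset = rng.uniform(-slack, slack, 2)
        while np.hypot(*offset) > slack:
            offset = rng.uniform(-slack, slack, 2)
        _paint_disc(fluor, center + offset, nr, 200.0)
        _label_disc(nucleus_labels, center + offset, nr, i)
    fluor8 = Image8(np.clip(np.rint(fluor), 0, 255).astype(np.uint8),
                    pixel_size=spec.pixel_size)

    truth = GroundTruth(centers=centers, radii=radii,
                        nucleus_labels=nucleus_labels,
                        noise_labels=noise_labels,
                        true_count=spec.n_cells)
    return pc8, fluor8, truth


@dataclass
class SceneRecord:
    """One scheduled image in a synthetic growth experiment."""

    time_h: float
    replicate: int
    image_index: int
    n_cells: int
    seed: int

    def spec(self, base: SceneSpec) -> SceneSpec:
        return replace(base, n_cells=self.n_cells, seed=self.seed)


@dataclass
class ExperimentManifest:
    """Schedule of scenes emulating an exponentially growing culture."""

    doubling_time_h: float
    times_h: list[float]
    replicates: int
    images_per_timepoint: int
    base_spec: SceneSpec
    records: list[SceneRecord]

    def counts_by_time_replicate(self) -> dict[tuple[float, int], list[int]]:
        out: dict[tuple[float, int], list[int]] = {}
        for rec in self.records:
            out.setdefault((rec.time_h, rec.replicate), []).append(rec.n_cells)
        return out


def generate_experiment(doubling_time_h: float, times_h, replicates: int,
                        images_per_timepoint: int, base_spec: SceneSpec,
                        seed: int = 0) -> ExperimentManifest:
    """Schedule scenes for an exponential-growth imaging experiment.

    The expected number of cells per field at time ``t`` is
    ``base_spec.n_cells * 2**(t / doubling_time_h)`` (``base_spec.n_cells``
    is the expected count at t = 0); each image's actual count is Poisson
    around that expectation, emulating random field-of-view placement in a
    nonuniform culture.
    """
    times_h = [float(t) for t in times_h]
    if doubling_time_h <= 0:
        raise ParameterError("doubling time must be positive")
    if any(b <= a for a, b in zip(times_h, times_h[1:])):
        raise ParameterError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    records = []
    for t in times_h:
        expected = base_spec.n_cells * 2.0 ** (t / doubling_time_h)
        feasible = _max_packing(base_spec)
        if expected > 0.8 * feasible:
            raise GenerationError(
                f"expected {expected:.0f} cells per field at t={t} h exceeds "
                f"packing capacity (~{feasible}); shrink the cells or field "
                "occupancy")
        for rep in range(replicates):
            for img in range(images_per_timepoint):
                n = int(rng.poisson(expected))
                records.append(SceneRecord(
                    time_h=t, replicate=rep, image_index=img, n_cells=n,
                    seed=int(rng.integers(0, 2**31 - 1))))
    return ExperimentManifest(doubling_time_h=doubling_time_h, times_h=times_h,
                              replicates=replicates,
                              images_per_timepoint=images_per_timepoint,
                              base_spec=base_spec, records=records)


def _max_packing(spec: SceneSpec) -> int:
    h, w = spec.shape
    margin = spec.cell_radius_mean + 3.0 * spec.halo_width + 2
    usable = max(h - 2 * margin, 0) * max(w - 2 * margin, 0)
    per_cell = spec.spacing ** 2  # square-lattice packing bound
    return int(usable / per_cell) if per_cell > 0 else 0


def write_experiment(manifest: ExperimentManifest, out_dir) -> str:
    """Render every scheduled scene to TIFF pairs plus a YAML manifest.

    Returns the manifest path.  Layout: ``t{time}_r{rep}_i{idx}_pc.tif``
    and ``..._fluor.tif`` under ``out_dir``.
    """
    import os

    from .image_io import write_image

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for rec in manifest.records:
        pc, fluor, _ = generate_scene(rec.spec(manifest.base_spec))
        stem = f"t{rec.time_h:g}_r{rec.replicate}_i{rec.image_index}"
        pc_path = os.path.join(out_dir, stem + "_pc.tif")
        fl_path = os.path.join(out_dir, stem + "_fluor.tif")
        write_image(pc, pc_path)
        write_image(fluor, fl_path)
        entries.append({"time_h": rec.time_h, "replicate": rec.replicate,
                        "image_index": rec.image_index,
                        "true_count": rec.n_cells,
                        "pc": os.path.basename(pc_path),
                        "fluor": os.path.basename(fl_path)})
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({
            "doubling_time_h": manifest.doubling_time_h,
            "times_h": manifest.times_h,
            "replicates": manifest.replicates,
            "images_per_timepoint": manifest.images_per_timepoint,
            "pixel_size_um": manifest.base_spec.pixel_size,
            "images": entries,
        }, fh, sort_keys=False)
    return manifest_path
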
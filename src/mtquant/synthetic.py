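"""Synthetic ground-truth data for every pipeline stage.

Three generators emulate the three kinds of raw data the pipeline consumes:

* :func:`simulate_sliding_movie` — a photoconversion pulse-chase timelapse.
  Microtubules are modelled as rigid line segments; at t=0 the converted
  signal is the geometric intersection of each filament with a disc-shaped
  conversion zone, and a chosen fraction of filaments then translocates
  rigidly at constant velocity.  The analytically computed fraction of
  converted filament length outside the zone at each frame is returned as
  ground truth, alongside a rendered stack (line rasterization → Gaussian
  PSF blur → exponential photobleaching → shot/read noise).

* :func:`simulate_coloc_image` — a two-channel still: channel 1 carries the
  microtubule filaments, channel 2 carries decoration (e.g. a
  microtubule-associated protein) placed on an exact, known share of the
  channel-1 filament pixels, chosen as contiguous runs along filaments.

* :func:`simulate_arbor` — a tree-structured neurite arbor of known total
  length and branch-point count, rendered as a thin bright skeleton.

All randomness flows from the integer ``seed`` carried by each parameter
object; identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import networkx as nx
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation as binary_dilation, disk as disk_footprint

from .prep import Movie

__all__ = [
    "SlidingSimParams",
    "SyntheticMovie",
    "ColocSimParams",
    "ColocSimResult",
    "ArborSimParams",
    "ArborSimResult",
    "simulate_sliding_movie",
    "simulate_coloc_image",
    "simulate_arbor",
]

# Rendered intensity per pixel of filament length, in arbitrary camera units.
# Chosen so that Poisson noise at scale 1 corresponds to ~100 photons per
# filament pixel, a realistic SNR for photoconverted tdEos/tdMaple signal.
_LINE_AMPLITUDE = 100.0

# Sub-pixel sampling step (pixels) for line splatting; small enough that the
# rendered integral of a segment is within rasterization tolerance of its
# exact length.
_SPLAT_STEP = 0.2


def _parse_noise(noise_model: str) -> tuple[str, float]:
    """Parse ``"none"``, ``"gaussian(sd)"`` or ``"poisson(scale)"``."""
    s = noise_model.strip().lower()
    if s == "none":
        return "none", 0.0
    for name in ("gaussian", "poisson"):
        if s.startswith(name + "(") and s.endswith(")"):
            try:
                value = float(s[len(name) + 1:-1])
            except ValueError as exc:
                raise ValueError(f"cannot parse noise model {noise_model!r}") from exc
            if value <= 0:
                raise ValueError(f"noise parameter must be > 0 in {noise_model!r}")
            return name, value
    raise ValueError(
        f"unknown noise model {noise_model!r}; expected 'none', 'gaussian(sd)' "
        f"or 'poisson(scale)'"
    )


def _apply_noise(frame: np.ndarray, kind: str, value: float,
                 rng: np.random.Generator) -> np.ndarray:
    if kind == "none":
        return frame
    if kind == "gaussian":
        return np.clip(frame + rng.normal(0.0, value, frame.shape), 0.0, None)
    if kind == "poisson":
        # value = expected photons at unit intensity
        return rng.poisson(np.clip(frame, 0.0, None) * value).astype(float) / value
    raise ValueError(kind)


def _splat_segment(image: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   amplitude: float) -> None:
    """Deposit ``amplitude`` per unit pixel length along segment p0→p1.

    Bilinear splatting at sub-pixel steps: total deposited intensity equals
    ``amplitude * |p1 - p0|`` exactly (up to float rounding) as long as the
    segment lies inside the image.
    """
    length = float(np.hypot(*(p1 - p0)))
    if length == 0.0:
        return
    n = max(int(math.ceil(length / _SPLAT_STEP)), 1)
    t = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    w = amplitude * length / n
    r, c = pts[:, 0], pts[:, 1]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr, fc = r - r0, c - c0
    h, wth = image.shape
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < wth)
        np.add.at(image, (rr[ok], cc[ok]), w * wt[ok])


def _segment_disc_interval(p0: np.ndarray, d: np.ndarray, length: float,
                           center: np.ndarray, radius: float
                           ) -> Optional[tuple[float, float]]:
    """Parameter interval [s0, s1] ⊂ [0, length] of p(s)=p0+s·d inside a disc.

    ``d`` must be a unit vector.  Returns ``None`` when the segment misses
    the disc.
    """
    f = p0 - center
    b = float(np.dot(f, d))
    c = float(np.dot(f, f)) - radius * radius
    disc = b * b - c
    if disc <= 0:
        return None
    root = math.sqrt(disc)
    s0, s1 = max(-b - root, 0.0), min(-b + root, length)
    if s1 <= s0:
        return None
    return s0, s1


def _inside_length(p0: np.ndarray, d: np.ndarray, length: float,
                   center: np.ndarray, radius: float) -> float:
    iv = _segment_disc_interval(p0, d, length, center, radius)
    return 0.0 if iv is None else iv[1] - iv[0]


@dataclass(frozen=True)
class SlidingSimParams:
    """Conditions of a simulated photoconversion sliding assay.

    Geometry is in pixel units (row, col), 0-based; physical quantities carry
    their units in the field name or docstring.
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_size: float = 0.1          # µm / pixel
    frame_interval: float = 1.0      # min / frame
    n_frames: int = 11
    n_filaments: int = 20
    filament_length_range: tuple[float, float] = (8.0, 12.0)  # µm
    motile_fraction_true: float = 0.1
    velocity: float = 0.15           # µm / min, motile filaments only
    zone_center: tuple[float, float] = (96.0, 96.0)           # pixels (row, col)
    zone_radius: float = 40.0        # pixels
    bleach_rate: float = 0.03        # per-frame fractional intensity loss
    psf_sigma: float = 1.0           # pixels
    noise_model: str = "poisson(1.0)"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.motile_fraction_true <= 1.0):
            raise ValueError("motile_fraction_true must be in [0, 1]")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if not (0.0 <= self.bleach_rate < 1.0):
            raise ValueError("bleach_rate must be in [0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        cy, cx = self.zone_center
        r = self.zone_radius
        h, w = self.image_shape
        if r <= 0 or cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
            raise ValueError("conversion zone must lie fully inside the image")
        _parse_noise(self.noise_model)


@dataclass
class SyntheticMovie:
    """A rendered sliding-assay movie with its geometric ground truth."""

    stack: np.ndarray                        # T × Y × X float intensities
    ground_truth_filaments: "np.ndarray"     # structured per filament per frame
    ground_truth_motile_fraction: np.ndarray  # per frame, analytic
    params: SlidingSimParams

    def to_movie(self) -> Movie:
        """Package the rendered stack as a pipeline :class:`~mtquant.prep.Movie`."""
        return Movie(stack=self.stack, pixel_size=self.params.pixel_size,
                     frame_interval=self.params.frame_interval)


_FILAMENT_DTYPE = np.dtype([
    ("filament", np.int32), ("frame", np.int32), ("motile", np.bool_),
    ("r0_um", np.float64), ("c0_um", np.float64),
    ("r1_um", np.float64), ("c1_um", np.float64),
])


def simulate_sliding_movie(params: SlidingSimParams) -> SyntheticMovie:
    """Simulate a photoconversion pulse-chase movie with known motile fraction.

    Filaments are rigid segments anchored so that each intersects the
    conversion zone; the converted material of a filament is its chord
    through the zone disc at t=0.  Motile filaments translocate along their
    own axis at ``params.velocity``; the ground-truth motile fraction at
    frame t is (converted length outside the zone) / (total converted
    length), computed from the unrendered geometry.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape
    center = np.asarray(p.zone_center, dtype=float)
    radius = float(p.zone_radius)
    lo_px, hi_px = (v / p.pixel_size for v in p.filament_length_range)

    n_motile = int(round(p.motile_fraction_true * p.n_filaments))
    if p.velocity > 0 and p.motile_fraction_true > 0 and n_motile == 0:
        warnings.warn(
            "motile_fraction_true * n_filaments < 1: no motile filament realized",
            stacklevel=2,
        )
    motile = np.zeros(p.n_filaments, dtype=bool)
    motile[rng.permutation(p.n_filaments)[:n_motile]] = True

    # Sample filament geometry: an anchor point uniform in the zone disc and
    # a uniform orientation; the filament is placed along that line so that
    # it spans the whole disc (microtubules are long relative to the
    # conversion spot), so every converted segment is a full chord with both
    # ends on the zone boundary.  This keeps the assay in its linear regime:
    # converted signal starts leaving the zone immediately, at a rate set by
    # the translocation velocity alone, with no lag phase from filament ends
    # buried inside the zone.
    seg_p0 = np.empty((p.n_filaments, 2))
    seg_dir = np.empty((p.n_filaments, 2))
    seg_len = np.empty(p.n_filaments)
    conv_p0 = np.empty((p.n_filaments, 2))
    conv_len = np.empty(p.n_filaments)
    move_dir = np.empty((p.n_filaments, 2))
    for i in range(p.n_filaments):
        rho = radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        anchor = center + rho * np.array([math.cos(phi), math.sin(phi)])
        theta = rng.uniform(0.0, 2.0 * math.pi)
        d = np.array([math.cos(theta), math.sin(theta)])
        # chord of the anchor's line through the zone disc
        f = anchor - center
        b = float(np.dot(f, d))
        root = math.sqrt(max(b * b - (float(np.dot(f, f)) - radius * radius),
                             0.0))
        s_lo, s_hi = -b - root, -b + root   # relative to the anchor
        chord = s_hi - s_lo
        L = max(rng.uniform(lo_px, hi_px), chord)
        u = rng.uniform()                   # filament slack beyond the chord
        p0 = anchor + (s_lo - u * (L - chord)) * d
        seg_p0[i], seg_dir[i], seg_len[i] = p0, d, L
        conv_p0[i] = anchor + s_lo * d
        conv_len[i] = chord
        move_dir[i] = d if rng.uniform() < 0.5 else -d

    noise_kind, noise_value = _parse_noise(p.noise_model)
    v_px = p.velocity / p.pixel_size  # pixels / min

    stack = np.zeros((p.n_frames,) + p.image_shape, dtype=np.float64)
    gt_fraction = np.zeros(p.n_frames)
    records = np.empty(p.n_frames * p.n_filaments, dtype=_FILAMENT_DTYPE)
    total_conv = float(conv_len.sum())

    rec = 0
    for t in range(p.n_frames):
        t_min = t * p.frame_interval
        frame = np.zeros(p.image_shape, dtype=np.float64)
        outside = 0.0
        for i in range(p.n_filaments):
            shift = (v_px * t_min * move_dir[i]) if motile[i] else 0.0
            q0 = conv_p0[i] + shift
            q1 = q0 + conv_len[i] * seg_dir[i]
            inside = _inside_length(q0, seg_dir[i], conv_len[i], center, radius)
            # clamp float residue from the quadratic chord solve
            outside += max(conv_len[i] - inside, 0.0) \
                if conv_len[i] - inside > 1e-9 else 0.0
            _splat_segment(frame, q0, q1, _LINE_AMPLITUDE)
            records[rec] = (
                i, t, motile[i],
                q0[0] * p.pixel_size, q0[1] * p.pixel_size,
                q1[0] * p.pixel_size, q1[1] * p.pixel_size,
            )
            rec += 1
        gt_fraction[t] = outside / total_conv if total_conv > 0 else 0.0
        frame = ndi.gaussian_filter(frame, p.psf_sigma)
        frame *= (1.0 - p.bleach_rate) ** t
        stack[t] = _apply_noise(frame, noise_kind, noise_value, rng)

    return SyntheticMovie(
        stack=stack,
        ground_truth_filaments=records,
        ground_truth_motile_fraction=gt_fraction,
        params=p,
    )


@dataclass(frozen=True)
class ColocSimParams:
    """Conditions of a simulated two-channel decoration still image."""

    image_shape: tuple[int, int] = (256, 256)
    n_filaments: int = 25
    decorated_fraction_true: float = 0.25
    filament_length_range: tuple[float, float] = (40.0, 90.0)  # pixels
    run_length: int = 50         # pixels per contiguous decorated run
    psf_sigma: float = 0.8       # pixels
    noise_model: str = "gaussian(2.0)"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.decorated_fraction_true <= 1.0):
            raise ValueError("decorated_fraction_true must be in [0, 1]")
        if self.n_filaments < 1 or self.run_length < 1:
            raise ValueError("n_filaments and run_length must be >= 1")
        _parse_noise(self.noise_model)


@dataclass
class ColocSimResult:
    channel1: np.ndarray          # rendered microtubule image
    channel2: np.ndarray          # rendered decoration image
    mt_mask_true: np.ndarray      # unblurred ground-truth filament pixels
    decorated_mask_true: np.ndarray  # unblurred ground-truth decorated pixels
    params: ColocSimParams

    @property
    def decorated_fraction_realized(self) -> float:
        """Achieved |decorated| / |filament| pixel ratio (run granularity)."""
        denom = int(self.mt_mask_true.sum())
        return float(self.decorated_mask_true.sum()) / denom if denom else 0.0


def simulate_coloc_image(params: ColocSimParams) -> ColocSimResult:
    """Render a microtubule channel and a decoration channel with known overlap.

    Channel-2 signal is placed on (to within one run's granularity) a
    ``decorated_fraction_true`` share of the channel-1 filament pixels,
    chosen by seeded sampling of contiguous pixel runs along filaments, then
    both channels are blurred and noised identically.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape
    margin = 4

    filament_pixels: list[np.ndarray] = []   # ordered (n,2) arrays per filament
    for _ in range(p.n_filaments):
        for _attempt in range(200):
            L = rng.uniform(*p.filament_length_range)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            d = np.array([math.cos(theta), math.sin(theta)])
            mid = np.array([rng.uniform(margin, h - 1 - margin),
                            rng.uniform(margin, w - 1 - margin)])
            p0 = mid - 0.5 * L * d
            p1 = mid + 0.5 * L * d
            if (p0 >= margin).all() and (p1 >= margin).all() \
                    and (p0 < [h - margin, w - margin]).all() \
                    and (p1 < [h - margin, w - margin]).all():
                rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])),
                                   int(round(p1[0])), int(round(p1[1])))
                filament_pixels.append(np.column_stack([rr, cc]))
                break
        else:  # pragma: no cover - geometry almost always fits
            raise RuntimeError("could not place filament inside image")

    mt_mask = np.zeros(p.image_shape, dtype=bool)
    for px in filament_pixels:
        mt_mask[px[:, 0], px[:, 1]] = True
    n_mt = int(mt_mask.sum())
    target = int(round(p.decorated_fraction_true * n_mt))

    # Split each filament's ordered pixel chain into contiguous runs, shuffle
    # the runs, and fill the decorated mask greedily to the target count.
    runs: list[np.ndarray] = []
    for px in filament_pixels:
        for start in range(0, len(px), p.run_length):
            runs.append(px[start:start + p.run_length])
    order = rng.permutation(len(runs))
    decorated = np.zeros(p.image_shape, dtype=bool)
    placed = 0
    for idx in order:
        if placed >= target:
            break
        for r, c in runs[idx]:
            if placed >= target:
                break
            if mt_mask[r, c] and not decorated[r, c]:
                decorated[r, c] = True
                placed += 1

    noise_kind, noise_value = _parse_noise(p.noise_model)

    def render(mask: np.ndarray) -> np.ndarray:
        img = ndi.gaussian_filter(mask.astype(float) * _LINE_AMPLITUDE,
                                  p.psf_sigma)
        return _apply_noise(img, noise_kind, noise_value, rng)

    return ColocSimResult(
        channel1=render(mt_mask),
        channel2=render(decorated),
        mt_mask_true=mt_mask,
        decorated_mask_true=decorated,
        params=p,
    )


@dataclass(frozen=True)
class ArborSimParams:
    """Conditions of a simulated tree-structured neurite arbor."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5             # µm / pixel
    n_branch_events: int = 8
    segment_length_range: tuple[float, float] = (15.0, 40.0)  # µm
    min_branch_separation: float = 6.0  # pixels between branch points
    dilation_radius: int = 1            # pixels; 0 renders the bare skeleton
    psf_sigma: float = 1.0              # pixels; 0 disables blur
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branch_events < 0:
            raise ValueError("n_branch_events must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.segment_length_range[0] <= 0:
            raise ValueError("segment lengths must be > 0")


@dataclass
class ArborSimResult:
    image: np.ndarray                  # rendered arbor
    ground_truth_length: float         # µm, sum of segment lengths
    ground_truth_branch_points: int    # internal nodes of degree >= 3
    tree: nx.Graph                     # node attr 'pos' = (row, col) pixels
    params: ArborSimParams


def simulate_arbor(params: ArborSimParams) -> ArborSimResult:
    """Grow a random planar tree by recursive tip branching and render it.

    Each branch event splits one growing tip into two daughter segments, so
    the number of degree-≥3 nodes equals ``n_branch_events`` whenever all
    growth succeeds.  New segments are rejected (and regrown, with lengths
    shrinking after repeated failures) when they leave the image, pass too
    close to existing structure, or put a branch point within
    ``min_branch_separation`` pixels of another.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape
    margin = 6.0
    clearance = 6.0  # self-avoidance distance between dendrites (px); DA-neuron
    # arbors tile without crossing, and separations below the PSF+closing
    # scale would not be resolvable as distinct branches anyway

    lo_px = p.segment_length_range[0] / p.pixel_size
    hi_px = p.segment_length_range[1] / p.pixel_size

    tree = nx.Graph()
    root = np.array([h / 2.0, w / 2.0])
    tree.add_node(0, pos=tuple(root))
    occupied: list[np.ndarray] = [root[None, :]]
    next_id = 1
    branch_points: list[np.ndarray] = []

    def seg_points(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        n = max(int(np.hypot(*(b - a))), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        return a[None, :] + t[:, None] * (b - a)[None, :]

    def fits(a: np.ndarray, b: np.ndarray) -> bool:
        if not (margin <= b[0] < h - margin and margin <= b[1] < w - margin):
            return False
        pts = seg_points(a, b)
        # ignore samples near the shared start node when testing clearance
        far = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1]) > 2.0 * clearance
        if not far.any():
            return True
        kd = cKDTree(np.vstack(occupied))
        dmin, _ = kd.query(pts[far], k=1)
        return bool(np.min(dmin) > clearance)

    def grow(a: np.ndarray, direction: float, length: float
             ) -> Optional[np.ndarray]:
        b = a + length * np.array([math.cos(direction), math.sin(direction)])
        return b if fits(a, b) else None

    # trunk
    total_len_px = 0.0
    trunk_dir = rng.uniform(0.0, 2.0 * math.pi)
    trunk_len = rng.uniform(lo_px, hi_px)
    b = None
    for attempt in range(100):
        trunk_dir = rng.uniform(0.0, 2.0 * math.pi)
        b = grow(root, trunk_dir, trunk_len * (0.95 ** attempt))
        if b is not None:
            trunk_len = trunk_len * (0.95 ** attempt)
            break
    if b is None:
        raise RuntimeError("arbor growth failed: trunk does not fit")
    tree.add_node(next_id, pos=tuple(b))
    tree.add_edge(0, next_id, length_px=trunk_len)
    occupied.append(seg_points(root, b))
    total_len_px += trunk_len
    tips: list[tuple[int, float]] = [(next_id, trunk_dir)]
    next_id += 1

    for _event in range(p.n_branch_events):
        placed = False
        for attempt in range(100):
            if not tips:
                break
            k = int(rng.integers(len(tips)))
            node, incoming = tips[k]
            pos = np.asarray(tree.nodes[node]["pos"])
            if branch_points and cKDTree(np.vstack(branch_points)).query(
                    pos[None, :], k=1)[0][0] < p.min_branch_separation:
                tips.pop(k)
                continue
            shrink = max(0.95 ** attempt, 0.4)
            angles = incoming + rng.uniform(0.35, 0.9) * np.array([1.0, -1.0]) \
                * rng.uniform(0.7, 1.3, size=2)
            lengths = rng.uniform(lo_px, hi_px, size=2) * shrink
            kids = [grow(pos, a, l) for a, l in zip(angles, lengths)]
            if kids[0] is None or kids[1] is None:
                continue
            # the two daughters must also clear each other (past the fork)
            pts0 = seg_points(pos, kids[0])[4:]
            pts1 = seg_points(pos, kids[1])[4:]
            if len(pts0) and len(pts1):
                d01 = np.min(np.hypot(
                    *(pts0.T[:, :, None] - pts1.T[:, None, :])))
                if d01 <= clearance:
                    continue
            tips.pop(k)
            branch_points.append(pos)
            for child, a, l in zip(kids, angles, lengths):
                tree.add_node(next_id, pos=tuple(child))
                tree.add_edge(node, next_id, length_px=l)
                occupied.append(seg_points(pos, child))
                total_len_px += l
                tips.append((next_id, a))
                next_id += 1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "arbor growth failed after 100 attempts at a branch event")

    # rasterize 1-px-wide, then optional dilation + blur
    mask = np.zeros(p.image_shape, dtype=bool)
    for u, v in tree.edges:
        (r0, c0), (r1, c1) = tree.nodes[u]["pos"], tree.nodes[v]["pos"]
        rr, cc = draw_line(int(round(r0)), int(round(c0)),
                           int(round(r1)), int(round(c1)))
        mask[rr, cc] = True
    if p.dilation_radius > 0:
        mask = binary_dilation(mask, disk_footprint(p.dilation_radius))
    image = mask.astype(float) * _LINE_AMPLITUDE
    if p.psf_sigma > 0:
        image = ndi.gaussian_filter(image, p.psf_sigma)

    n_branch = sum(1 for n in tree.nodes if tree.degree[n] >= 3)
    return ArborSimResult(
        image=image,
        ground_truth_length=total_len_px * p.pixel_size,
        ground_truth_branch_points=n_branch,
        tree=tree,
        params=p,
    )


def zone_mask(params: SlidingSimParams) -> np.ndarray:
    """Boolean mask of the simulated conversion zone disc."""
    mask = np.zeros(params.image_shape, dtype=bool)
    rr, cc = draw_disk(params.zone_center, params.zone_radius,
                       shape=params.image_shape)
    mask[rr, cc] = True
    return mask
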
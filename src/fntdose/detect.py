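"""Per-slice spot detection and 3D track reconstruction.

A detector readout is an 11-slice confocal stack (512 x 512 px covering
100 um x 100 um, slices at 2, 4, ..., 22 um nominal depth).  Each ionizing
track appears as one fluorescent spot per slice, laterally displaced by
dz * tan(theta) between slices along the track azimuth.  The pipeline is:

1. ``detect_spots``: robust per-slice thresholding (median + k * MAD) and
   connected-component labelling; each spot carries a sub-pixel refined peak
   intensity (background subtracted) and an intensity-weighted centroid.
2. ``link_spots``: greedy nearest-neighbour association between consecutive
   slices with a slope-limited search radius, explicit handling of contested
   spots (two chains wanting the same spot, e.g. crossing tracks), and a
   directional-consistency check while walking chains.
3. ``compute_track_geometry``: total-least-squares line fit of the spot
   centroids versus depth, giving polar angle, azimuth and depth extent.
4. ``compute_track_intensity``: mean of the per-slice peak intensities from
   the second to the penultimate occupied slice (defined only for tracks
   spanning >= 3 slices).
5. ``classify_track``: delta-electron stubs (<= 4 consecutive slices),
   alpha-reference tracks (alpha region, depth <= 16 um), overlap-rejected
   chains, ions otherwise.

Chains that share a contested spot, or approach another chain closer than a
minimum separation in any slice, are classified ``rejected_overlap`` and
excluded from intensity-based quantities downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import ConfigurationError, DataError

__all__ = [
    "ImageStack",
    "Spot",
    "Track",
    "DetectionParams",
    "LinkingParams",
    "ClassificationParams",
    "detect_spots",
    "link_spots",
    "compute_track_geometry",
    "compute_track_intensity",
    "classify_track",
    "extract_tracks",
    "tracks_to_table",
]


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

DEFAULT_SLICE_DEPTHS_UM = tuple(np.arange(2.0, 24.0, 2.0))  # 2, 4, ..., 22
DEFAULT_PIXEL_UM = 100.0 / 512.0


@dataclass
class ImageStack:
    """Slice-ordered 3D intensity volume with its readout geometry."""

    voxels: np.ndarray                       # (n_slices, ny, nx), a.u.
    slice_depths_um: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_SLICE_DEPTHS_UM))
    pixel_um: float = DEFAULT_PIXEL_UM
    detector_id: str = ""
    region: str = "out_of_field"             # or "alpha_ref"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.slice_depths_um = np.asarray(self.slice_depths_um, dtype=float)
        if self.voxels.ndim != 3:
            raise DataError("voxels must be a (n_slices, ny, nx) array")
        if self.voxels.shape[0] != self.slice_depths_um.size:
            raise DataError("number of slices must match slice_depths_um")
        if np.any(np.diff(self.slice_depths_um) <= 0):
            raise DataError("slice depths must be strictly increasing")
        if self.region not in ("out_of_field", "alpha_ref"):
            raise ConfigurationError(f"unknown region label {self.region!r}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.voxels.shape[2] * self.pixel_um,
                self.voxels.shape[1] * self.pixel_um)

    @property
    def area_cm2(self) -> float:
        wx, wy = self.fov_um
        return wx * wy * 1e-8

    # -- TIFF round trip ---------------------------------------------------
    def to_tiff(self, path):
        meta = {
            "slice_depths_um": self.slice_depths_um.tolist(),
            "pixel_um": self.pixel_um,
            "detector_id": self.detector_id,
            "region": self.region,
        }
        tifffile.imwrite(
            path,
            np.clip(np.rint(self.voxels), 0, 65535).astype(np.uint16),
            photometric="minisblack",
            description=json.dumps(meta),
        )

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            voxels = tif.asarray()
            desc = tif.pages[0].description
        kwargs = {}
        if desc:
            try:
                meta = json.loads(desc)
                kwargs = {
                    "slice_depths_um": np.asarray(meta["slice_depths_um"]),
                    "pixel_um": float(meta["pixel_um"]),
                    "detector_id": meta.get("detector_id", ""),
                    "region": meta.get("region", "out_of_field"),
                }
            except (json.JSONDecodeError, KeyError):
                pass
        return cls(voxels=voxels, **kwargs)


@dataclass
class Spot:
    """One detected fluorescent spot in one slice."""

    slice_index: int
    centroid_xy_um: tuple[float, float]
    max_intensity: float     # background-subtracted, sub-pixel refined peak
    area_px: int


@dataclass
class Track:
    """A chain of spots in consecutive slices forming one particle track."""

    spots: list[Spot]
    polar_deg: float = float("nan")
    azimuth_deg: float = float("nan")
    intensity: float | None = None
    classification: str = ""
    path_depth_um: float = float("nan")
    overlap: bool = False
    track_id: int = -1

    @property
    def n_slices_spanned(self) -> int:
        return len(self.spots)


@dataclass
class DetectionParams:
    threshold_k: float = 5.0        # threshold = median + k * MAD
    min_threshold_au: float = 30.0  # absolute floor above background
    min_area_px: int = 4
    refine_peak: bool = True


@dataclass
class LinkingParams:
    r0_um: float = 1.0              # search radius at zero slope
    theta_max_link_deg: float = 75.0
    direction_tol_deg: float = 30.0
    min_separation_um: float = 1.5  # same-slice proximity => overlap


@dataclass
class ClassificationParams:
    delta_max_slices: int = 4
    alpha_max_range_um: float = 16.0


# --------------------------------------------------------------------------
# Spot detection
# --------------------------------------------------------------------------

def _refine_peak(img_bs: np.ndarray, r: int, c: int) -> float:
    """Sub-pixel peak estimate by separable log-parabola interpolation
    through the maximum pixel and its 4-neighbours.  Exact for a sampled
    Gaussian; falls back to the raw maximum near edges or invalid values."""
    peak = img_bs[r, c]
    if peak <= 0:
        return float(peak)
    log_corr = 0.0
    for (l, hgh) in (((r, c - 1), (r, c + 1)), ((r - 1, c), (r + 1, c))):
        (r0, c0), (r1, c1) = l, hgh
        if not (0 <= r0 < img_bs.shape[0] and 0 <= c0 < img_bs.shape[1]
                and 0 <= r1 < img_bs.shape[0] and 0 <= c1 < img_bs.shape[1]):
            continue
        lo, hi = img_bs[r0, c0], img_bs[r1, c1]
        if lo <= 0 or hi <= 0 or lo > peak or hi > peak:
            continue
        ll, lc, lh = np.log(lo), np.log(peak), np.log(hi)
        q = ll - 2 * lc + lh            # 2nd difference, <= 0 at a maximum
        if q >= 0:
            continue
        log_corr += -((lh - ll) ** 2) / (8.0 * q)
    refined = float(peak * np.exp(min(log_corr, np.log(2.0))))
    return refined


def detect_spots(
    slice_img: np.ndarray,
    params: DetectionParams | None = None,
    pixel_um: float = DEFAULT_PIXEL_UM,
    slice_index: int = 0,
) -> list[Spot]:
    """Detect fluorescent spots in a single slice.

    Background is the slice median; the detection threshold is
    ``median + k * MAD``.  Connected components above threshold and at least
    ``min_area_px`` pixels large become spots, sorted by position for
    determinism.  An all-constant slice yields no spots.
    """
    params = params or DetectionParams()
    img = np.asarray(slice_img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DataError("slice contains non-finite values")
    bg = np.median(img)
    mad = np.median(np.abs(img - bg))
    thr = bg + max(params.threshold_k * mad, params.min_threshold_au)
    mask = img > thr
    if not mask.any():
        return []
    img_bs = img - bg
    labels = measure.label(mask, connectivity=2)
    spots = []
    for region in measure.regionprops(labels, intensity_image=img_bs):
        if region.area < params.min_area_px:
            continue
        ry, rx = region.centroid_weighted
        # brightest pixel of the component
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        k = np.argmax(img_bs[rr, cc])
        if params.refine_peak:
            peak = _refine_peak(img_bs, int(rr[k]), int(cc[k]))
        else:
            peak = float(img_bs[rr[k], cc[k]])
        spots.append(Spot(
            slice_index=slice_index,
            centroid_xy_um=((rx + 0.5) * pixel_um, (ry + 0.5) * pixel_um),
            max_intensity=peak,
            area_px=int(region.area),
        ))
    spots.sort(key=lambda s: (s.centroid_xy_um[1], s.centroid_xy_um[0]))
    return spots


# --------------------------------------------------------------------------
# Linking
# --------------------------------------------------------------------------

def _angle_between(v1, v2) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def link_spots(
    spots_per_slice: Sequence[Sequence[Spot]],
    slice_depths_um: Sequence[float],
    params: LinkingParams | None = None,
) -> list[Track]:
    """Link per-slice spots into 3D chains across consecutive slices.

    Association between slice j and j+1 is greedy nearest-neighbour within a
    slope-limited radius ``r0 + dz * tan(theta_max)``; every spot joins at
    most one primary chain.  When a spot is contested (a second chain's best
    continuation is an already-taken spot, as happens where tracks cross),
    a secondary link is recorded, the spot is marked contested, and every
    chain passing through it is flagged for overlap rejection.  A second
    overlap criterion flags chains that approach each other closer than
    ``min_separation_um`` in any slice, where spot intensities blend.

    Unlinked spots are returned as single-spot chains.  The result is
    invariant to the input ordering of spots within a slice.
    """
    params = params or LinkingParams()
    depths = np.asarray(slice_depths_um, dtype=float)
    n_slices = len(depths)
    if len(spots_per_slice) != n_slices:
        raise DataError("spots_per_slice length must match slice_depths_um")

    # canonical ordering for determinism
    per_slice: list[list[Spot]] = []
    for j, spots in enumerate(spots_per_slice):
        s = sorted(spots, key=lambda s: (s.centroid_xy_um[1], s.centroid_xy_um[0]))
        for sp in s:
            if sp.slice_index != j:
                sp.slice_index = j
        per_slice.append(s)

    # node bookkeeping: (slice, idx) -> spot
    def pos(node):
        sp = per_slice[node[0]][node[1]]
        return np.array([sp.centroid_xy_um[0], sp.centroid_xy_um[1], depths[node[0]]])

    edges_out: dict[tuple, list] = {}
    edges_in: dict[tuple, list] = {}
    tan_max = np.tan(np.radians(params.theta_max_link_deg))

    for j in range(n_slices - 1):
        a, b = per_slice[j], per_slice[j + 1]
        if not a or not b:
            continue
        dz = depths[j + 1] - depths[j]
        radius = params.r0_um + dz * tan_max
        pa = np.array([s.centroid_xy_um for s in a])
        pb = np.array([s.centroid_xy_um for s in b])
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        cand = np.argwhere(d <= radius)
        if cand.size == 0:
            continue
        order = np.lexsort((cand[:, 1], cand[:, 0], d[cand[:, 0], cand[:, 1]]))
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        # primary greedy one-to-one matching by distance (ties: lowest index)
        for k in order:
            ia, ib = int(cand[k, 0]), int(cand[k, 1])
            if ia in taken_a or ib in taken_b:
                continue
            taken_a.add(ia)
            taken_b.add(ib)
            edges_out.setdefault((j, ia), []).append(((j + 1, ib), d[ia, ib], True))
            edges_in.setdefault((j + 1, ib), []).append(((j, ia), d[ia, ib], True))
        # secondary links for losers of a contested spot
        by_a: dict[int, list] = {}
        by_b: dict[int, list] = {}
        for ia, ib in cand:
            by_a.setdefault(int(ia), []).append(int(ib))
            by_b.setdefault(int(ib), []).append(int(ia))
        for ia, cands in by_a.items():
            if ia in taken_a:
                continue
            ib = min(cands, key=lambda ib: (d[ia, ib], ib))
            edges_out.setdefault((j, ia), []).append(((j + 1, ib), d[ia, ib], False))
            edges_in.setdefault((j + 1, ib), []).append(((j, ia), d[ia, ib], False))
        for ib, cands in by_b.items():
            if ib in taken_b:
                continue
            ia = min(cands, key=lambda ia: (d[ia, ib], ia))
            edges_out.setdefault((j, ia), []).append(((j + 1, ib), d[ia, ib], False))
            edges_in.setdefault((j + 1, ib), []).append(((j, ia), d[ia, ib], False))

    # ---- walk chains ------------------------------------------------------
    consumed: set[tuple] = set()     # consumed edges (src, dst)
    visited_roots: set[tuple] = set()
    chains: list[list[tuple]] = []

    all_nodes = [(j, i) for j in range(n_slices) for i in range(len(per_slice[j]))]
    roots = [n for n in all_nodes if n not in edges_in]
    # nodes whose incoming edges were all dropped become roots later
    pending = list(roots)
    used_in_chain: dict[tuple, int] = {}

    def walk(start):
        chain = [start]
        direction = None
        node = start
        while True:
            outs = [e for e in edges_out.get(node, [])
                    if (node, e[0]) not in consumed]
            if not outs:
                break
            if direction is None:
                nxt = min(outs, key=lambda e: (not e[2], e[1], e[0]))
            else:
                scored = []
                for e in outs:
                    v = pos(e[0]) - pos(node)
                    ang = _angle_between(direction, v)
                    scored.append((ang, not e[2], e[1], e[0], e))
                scored.sort(key=lambda t: t[:4])
                best = scored[0]
                if best[0] > params.direction_tol_deg:
                    break
                nxt = best[4]
            consumed.add((node, nxt[0]))
            v = pos(nxt[0]) - pos(node)
            direction = v if direction is None else 0.5 * (direction + v)
            chain.append(nxt[0])
            node = nxt[0]
        return chain

    for start in sorted(pending):
        if start in visited_roots:
            continue
        visited_roots.add(start)
        chains.append(walk(start))

    # nodes never reached (e.g. all incoming edges consumed by other chains,
    # or dropped by the direction check) start their own chains
    reached = {n for ch in chains for n in ch}
    leftovers = sorted(n for n in all_nodes if n not in reached)
    for node in leftovers:
        if node in reached:
            continue
        ch = walk(node)
        chains.append(ch)
        reached.update(ch)

    # ---- build Track objects ----------------------------------------------
    tracks: list[Track] = []
    node_to_tracks: dict[tuple, list[int]] = {}
    for tid, ch in enumerate(chains):
        spots = [per_slice[j][i] for (j, i) in ch]
        tr = Track(spots=spots, track_id=tid)
        tracks.append(tr)
        for n in ch:
            node_to_tracks.setdefault(n, []).append(tid)

    # spots shared between chains -> overlap
    for n, tids in node_to_tracks.items():
        if len(tids) > 1:
            for t in tids:
                tracks[t].overlap = True

    # same-slice proximity between different chains -> overlap
    for j in range(n_slices):
        nodes = [(j, i) for i in range(len(per_slice[j]))]
        if len(nodes) < 2:
            continue
        pts = np.array([per_slice[j][i].centroid_xy_um for (_, i) in nodes])
        dd = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        close = np.argwhere((dd < params.min_separation_um) & (dd > 0))
        for i1, i2 in close:
            t1s = node_to_tracks.get(nodes[i1], [])
            t2s = node_to_tracks.get(nodes[i2], [])
            if set(t1s) != set(t2s):
                for t in set(t1s) | set(t2s):
                    tracks[t].overlap = True
    return tracks


# --------------------------------------------------------------------------
# Geometry, intensity, classification
# --------------------------------------------------------------------------

def compute_track_geometry(track: Track, slice_depths_um: Sequence[float]):
    """Polar angle, azimuth and depth extent from a total-least-squares line
    fit of the spot centroids versus depth.

    The direction is the principal axis (SVD) of the centred 3D centroid
    cloud, oriented into the crystal.  Identical centroids at different
    depths give theta = 0 exactly.
    """
    depths = np.asarray(slice_depths_um, dtype=float)
    if track.n_slices_spanned < 2:
        track.polar_deg = float("nan")
        track.azimuth_deg = float("nan")
        track.path_depth_um = 0.0
        return track.polar_deg, track.azimuth_deg, track.path_depth_um
    pts = np.array([
        [s.centroid_xy_um[0], s.centroid_xy_um[1], depths[s.slice_index]]
        for s in track.spots
    ])
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred[:, :2], 0.0):
        direction = np.array([0.0, 0.0, 1.0])
    else:
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]
        if direction[2] < 0:
            direction = -direction
    nz = abs(direction[2]) / np.linalg.norm(direction)
    polar = float(np.degrees(np.arccos(np.clip(nz, 0.0, 1.0))))
    azim = float(np.degrees(np.arctan2(direction[1], direction[0])) % 360.0)
    track.polar_deg = polar
    track.azimuth_deg = azim
    track.path_depth_um = float(pts[:, 2].max() - pts[:, 2].min())
    return polar, azim, track.path_depth_um


def compute_track_intensity(track: Track) -> float | None:
    """Track intensity: arithmetic mean of the per-slice peak intensities
    from the second to the penultimate occupied slice.  Undefined (None) for
    tracks spanning fewer than 3 slices, which remain classifiable as delta
    stubs."""
    if track.n_slices_spanned < 3:
        track.intensity = None
        return None
    maxima = [s.max_intensity for s in
              sorted(track.spots, key=lambda s: s.slice_index)]
    track.intensity = float(np.mean(maxima[1:-1]))
    return track.intensity


def classify_track(
    track: Track,
    region: str,
    slice_depths_um: Sequence[float],
    params: ClassificationParams | None = None,
) -> str:
    """Assign one of {ion, delta, alpha_ref, rejected_overlap}.

    Overlap flags take precedence.  In the alpha-reference region a track
    whose deepest spot stays within the alpha range (16 um) is an alpha
    reference track; deeper tracks there are out-of-field ions leaking into
    the region.  In the out-of-field region short stubs (<= 4 consecutive
    slices) are delta electrons.
    """
    params = params or ClassificationParams()
    depths = np.asarray(slice_depths_um, dtype=float)
    if track.overlap:
        track.classification = "rejected_overlap"
        return track.classification
    max_depth = max(depths[s.slice_index] for s in track.spots)
    if region == "alpha_ref":
        label = ("alpha_ref" if max_depth <= params.alpha_max_range_um
                 else "ion")
    else:
        label = ("delta" if track.n_slices_spanned <= params.delta_max_slices
                 else "ion")
    track.classification = label
    return label


# --------------------------------------------------------------------------
# Convenience: whole-stack extraction and table output
# --------------------------------------------------------------------------

def extract_tracks(
    stack: ImageStack,
    detection: DetectionParams | None = None,
    linking: LinkingParams | None = None,
    classification: ClassificationParams | None = None,
) -> list[Track]:
    """Detect, link, measure and classify all tracks in a stack."""
    detection = detection or DetectionParams()
    spots_per_slice = [
        detect_spots(stack.voxels[j], detection, stack.pixel_um, slice_index=j)
        for j in range(stack.n_slices)
    ]
    tracks = link_spots(spots_per_slice, stack.slice_depths_um, linking)
    for tr in tracks:
        compute_track_geometry(tr, stack.slice_depths_um)
        compute_track_intensity(tr)
        classify_track(tr, stack.region, stack.slice_depths_um, classification)
    return tracks


def tracks_to_table(tracks: Sequence[Track], detector_id: str = "",
                    region: str = "out_of_field") -> pd.DataFrame:
    """Track table in the exchange layout used by the CLI (TSV)."""
    rows = []
    for tr in tracks:
        rows.append({
            "track_id": tr.track_id,
            "detector_id": detector_id,
            "region": region,
            "n_slices": tr.n_slices_spanned,
            "polar_deg": tr.polar_deg,
            "azimuth_deg": tr.azimuth_deg,
            "intensity_au": np.nan if tr.intensity is None else tr.intensity,
            "classification": tr.classification,
            "path_depth_um": tr.path_depth_um,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "detector_id", "region", "n_slices", "polar_deg",
        "azimuth_deg", "intensity_au", "classification", "path_depth_um",
    ])
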
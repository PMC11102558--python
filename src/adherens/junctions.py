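"""The operator chain from a raw cadherin-5 channel to closed cell outlines.

An intact endothelial monolayer shows VE-cadherin as a continuous ridge along
every cell–cell border. To score each cell, the junction network must first
be turned into a clean one-pixel-wide skeleton whose enclosed faces are the
cells. The chain is deliberately conventional image processing — flatten
illumination, denoise, re-sharpen, auto-threshold, thicken, repair breaks,
thin — with every parameter exposed and every applied step recorded in the
skeleton's provenance:

    subtract_background -> gaussian_blur (x2) -> sharpen ->
    huang_threshold / binarize -> dilate_binary (x2) -> close_gaps ->
    skeletonize -> extract_cell_outlines -> select_outlines

The interactive touch-up step a microscopist would do by hand (drawing over
broken junctions) is replaced by :func:`close_gaps`, an automated endpoint
bridge with a bounded reach, so the pipeline is reproducible end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, restoration

from .image import ImageChannel, as_uint8

_SQUARE3 = np.ones((3, 3), dtype=bool)

# clockwise 8-neighborhood in image coordinates (row grows downward)
_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class JunctionSkeleton:
    """One-pixel-wide junction network plus the operator provenance."""

    skeleton_mask: np.ndarray
    provenance: list[str] = field(default_factory=list)


@dataclass
class CellOutline:
    """Closed, ordered pixel path delineating one cell.

    ``path`` is an (n, 2) array of row/col pixel coordinates; closure is
    implicit (last pixel is 8-adjacent to the first, which is not repeated).
    Outlines whose enclosing face touches the image frame are flagged and
    never enter scoring — a cell cut by the frame has no complete outline.
    """

    cell_id: int
    path: np.ndarray
    image_id: str = ""
    touches_border: bool = False

    def __len__(self) -> int:
        return len(self.path)


# ---------------------------------------------------------------------------
# intensity filters

def subtract_background(img: ImageChannel, radius: int = 20) -> ImageChannel:
    """Rolling-ball background subtraction (classic ball, radius in px).

    The background is the upper envelope of a ball of the given radius rolled
    under the intensity surface; subtracting it flattens slow illumination
    gradients while leaving thin bright ridges (junctions) intact. Output is
    clipped at 0 and never exceeds the input.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    bg = restoration.rolling_ball(img.pixels, radius=radius)
    out = np.clip(img.pixels.astype(np.float64) - bg, 0, 255)
    return img.with_pixels(as_uint8(out))


def gaussian_blur(img: ImageChannel, sigma: float = 2.0, passes: int = 2) -> ImageChannel:
    """Separable Gaussian smoothing applied ``passes`` times.

    Filtering is done in float and quantized once at the end, so repeated
    passes compose like a single pass at sigma * sqrt(passes).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    out = img.pixels.astype(np.float64)
    for _ in range(passes):
        out = ndi.gaussian_filter(out, sigma=sigma, mode="reflect")
    return img.with_pixels(as_uint8(out))


_SHARPEN_KERNEL = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]], dtype=np.float64) / 4.0


def sharpen(img: ImageChannel) -> ImageChannel:
    """3x3 unsharp filter (center 12, neighbors -1, divisor 4), clipped."""
    out = ndi.convolve(img.pixels.astype(np.float64), _SHARPEN_KERNEL, mode="nearest")
    return img.with_pixels(as_uint8(out))


def huang_threshold(img: ImageChannel) -> int:
    """Automatic threshold minimizing Huang's fuzziness criterion.

    For each candidate threshold t the image is split into a below class
    (<= t) and an above class (> t) with means mu0, mu1; each gray level g
    gets a membership u(g) = 1 / (1 + |g - mu_class| / C) with C the dynamic
    range, and the fuzziness is the histogram-weighted Shannon entropy of
    those memberships. The t with minimal fuzziness wins; ties break toward
    the smaller threshold.
    """
    hist = np.bincount(img.pixels.ravel(), minlength=256).astype(np.float64)
    nonzero = np.nonzero(hist)[0]
    if len(nonzero) < 2:
        raise ValueError("no threshold exists: image has a single intensity value")
    first, last = int(nonzero[0]), int(nonzero[-1])
    dynamic_range = float(last - first)
    levels = np.arange(256, dtype=np.float64)
    cum_h = np.cumsum(hist)
    cum_gh = np.cumsum(levels * hist)

    best_t, best_fuzz = first, np.inf
    for t in range(first, last):
        n_low = cum_h[t]
        n_high = cum_h[-1] - n_low
        mu_low = cum_gh[t] / n_low
        mu_high = (cum_gh[-1] - cum_gh[t]) / n_high
        mu = np.where(levels <= t, mu_low, mu_high)
        u = 1.0 / (1.0 + np.abs(levels - mu) / dynamic_range)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        ent[~np.isfinite(ent)] = 0.0  # u == 1: pixel exactly at its class mean
        fuzz = float(np.dot(hist, ent))
        if fuzz < best_fuzz - 1e-12:
            best_fuzz, best_t = fuzz, t
    return best_t


def binarize(img: ImageChannel, threshold: int) -> np.ndarray:
    """Foreground iff intensity strictly greater than the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return img.pixels > threshold


# ---------------------------------------------------------------------------
# binary morphology

def dilate_binary(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """8-connected (3x3) binary dilation; ``iterations=0`` is the identity."""
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=_SQUARE3, iterations=iterations)


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    counts = ndi.convolve(mask.astype(np.uint8), _SQUARE3.astype(np.uint8), mode="constant")
    return np.where(mask, counts - 1, 0)


def _geodesic_reach(skel_set: set, start: tuple[int, int], depth: int) -> set:
    """Pixels reachable from ``start`` along the skeleton within ``depth`` steps."""
    frontier = {start}
    seen = {start}
    for _ in range(depth):
        nxt = set()
        for r, c in frontier:
            for dr, dc in _CLOCKWISE:
                q = (r + dr, c + dc)
                if q in skel_set and q not in seen:
                    seen.add(q)
                    nxt.add(q)
        if not nxt:
            break
        frontier = nxt
    return seen


def close_gaps(mask: np.ndarray, max_bridge: int = 10, max_rounds: int = 8) -> np.ndarray:
    """Bridge breaks in the junction network with straight pen strokes.

    Stands in for the manual line-tool touch-up a microscopist would do.
    Loose ends of the thinned network are joined to a nearby network pixel —
    another loose end when one faces it, or the flank of a continuing border
    when the break sits at a three-way corner. ``max_bridge`` bounds the
    *uncovered* span the stroke crosses: the stroke may additionally run over
    pixels the (possibly thick) mask already covers, since thinning retracts
    blunt stub tips well inside the inked area. A target already connected
    to the endpoint by a short path along the network is skipped (that would
    merely fold a spur onto itself). Bridging is iterated: repairing one
    break can expose the partner of the next.

    Output is a superset of the input; ``max_bridge=0`` is the identity.
    """
    if max_bridge < 0:
        raise ValueError(f"max_bridge must be >= 0, got {max_bridge}")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if max_bridge == 0 or not mask.any():
        return out

    from scipy.spatial import cKDTree
    from skimage.draw import line as draw_line

    geo_depth = 3 * max_bridge
    search_radius = 3 * max_bridge
    for _ in range(max_rounds):
        skel = morphology.skeletonize(out)
        endpoints = np.argwhere(skel & (_neighbor_count(skel) == 1))
        if len(endpoints) == 0:
            break
        skel_pts = np.argwhere(skel)
        skel_set = {tuple(p) for p in skel_pts}
        tree = cKDTree(skel_pts)
        bridged = False
        for ep in endpoints:
            ep_t = (int(ep[0]), int(ep[1]))
            near_self = _geodesic_reach(skel_set, ep_t, geo_depth)
            idx = tree.query_ball_point(ep, search_radius)
            order = sorted(
                idx, key=lambda i: (np.hypot(*(skel_pts[i] - ep)), skel_pts[i][0], skel_pts[i][1])
            )
            best, best_key = None, (np.inf, np.inf)
            for i in order:
                q = (int(skel_pts[i][0]), int(skel_pts[i][1]))
                if q == ep_t or q in near_self:
                    continue
                rr, cc = draw_line(ep_t[0], ep_t[1], q[0], q[1])
                void = int((~out[rr, cc]).sum())
                if void > max_bridge:
                    continue
                key = (void, float(np.hypot(q[0] - ep_t[0], q[1] - ep_t[1])))
                if key < best_key:
                    best, best_key = (rr, cc), key
            if best is not None:
                out[best[0], best[1]] = True
                bridged = True
        if not bridged:
            break
    return out


# ---------------------------------------------------------------------------
# skeletonization with spur pruning

def _prune_spurs(skel: np.ndarray, prune_length: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``prune_length`` that hang off a
    branch point. Isolated short segments are kept, so the number of
    connected components never changes."""
    out = skel.copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbor_count(out)
        for r, c in np.argwhere(out & (counts == 1)):
            walk = [(int(r), int(c))]
            prev = None
            cur = (int(r), int(c))
            hit_branch = False
            while len(walk) <= prune_length:
                neighbors = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _CLOCKWISE
                    if 0 <= cur[0] + dr < out.shape[0]
                    and 0 <= cur[1] + dc < out.shape[1]
                    and out[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(neighbors) != 1:
                    hit_branch = len(neighbors) > 1
                    break
                prev, cur = cur, neighbors[0]
                if counts[cur] >= 3:
                    hit_branch = True
                    break
                walk.append(cur)
            if hit_branch and len(walk) < prune_length:
                for p in walk:
                    out[p] = False
                changed = True
        if changed:
            continue
    return out


def skeletonize(
    mask: np.ndarray, prune_length: int = 5, min_loop_area: int = 32
) -> JunctionSkeleton:
    """Topology-preserving thinning to 1-px curves, with short spurs pruned.

    Holes smaller than ``min_loop_area`` pixels are filled before thinning:
    they are far below any plausible cell face and would otherwise thin into
    tiny loops at junction corners (the same noise policy that discards
    outlines shorter than 20 px downstream). Thinning and pruning are then
    iterated to a joint fixed point, which makes the operation idempotent on
    its own output by construction. Connected components are preserved
    (pruning never deletes a whole component).
    """
    mask = np.asarray(mask, dtype=bool)
    if min_loop_area > 0:
        mask = morphology.remove_small_holes(mask, max_size=min_loop_area)
    skel = morphology.skeletonize(mask)
    for _ in range(20):
        pruned = _prune_spurs(skel, prune_length)
        thinned = morphology.skeletonize(pruned)
        if np.array_equal(thinned, skel):
            break
        skel = thinned
    return JunctionSkeleton(skel, provenance=[f"skeletonize(prune_length={prune_length})"])


# ---------------------------------------------------------------------------
# face tracing

def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered clockwise boundary of an 8-connected region (Moore tracing).

    Returns the boundary pixels as an (n, 2) array forming a closed
    8-connected loop; the start pixel appears once.
    """
    pts = np.argwhere(mask)
    if len(pts) == 0:
        return np.empty((0, 2), dtype=int)
    if len(pts) == 1:
        return pts.astype(int)
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])  # topmost-leftmost
    backtrack = (start[0], start[1] - 1)  # guaranteed background

    def in_mask(p):
        return 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]

    path = [start]
    cur, back = start, backtrack
    initial_state = (cur, back)
    max_steps = 4 * len(pts) + 8
    for _ in range(max_steps):
        # scan clockwise starting just after the backtrack position
        offsets = _CLOCKWISE
        back_dir = offsets.index((back[0] - cur[0], back[1] - cur[1]))
        moved = False
        for k in range(1, 9):
            d = offsets[(back_dir + k) % 8]
            q = (cur[0] + d[0], cur[1] + d[1])
            if in_mask(q):
                cur, moved = q, True
                break
            back = q
        if not moved:
            break  # isolated pixel cluster with no further boundary
        if (cur, back) == initial_state:
            break
        path.append(cur)
    if len(path) > 1 and path[-1] == start:
        path.pop()
    # drop revisits (possible at 1-px protrusions) while keeping order
    seen: set[tuple[int, int]] = set()
    unique = []
    for p in path:
        if p not in seen:
            seen.add(p)
            unique.append(p)
    return np.array(unique, dtype=int)


def _adj8(p, q) -> bool:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= 1


def _snap_path_to_skeleton(path: np.ndarray, skel: np.ndarray) -> np.ndarray:
    """Pull 1-px tracing jitter back onto the skeleton.

    The Moore trace of the dilated face steps one pixel inside the face at
    diagonal skeleton staircases. Each off-skeleton path pixel is replaced by
    an adjacent skeleton pixel when that keeps the loop 8-connected, or
    dropped when its neighbors already connect; otherwise it is kept.
    """
    n = len(path)
    if n < 3:
        return path
    pts = [tuple(p) for p in path]
    out: list[tuple[int, int]] = []
    taken = set(pts)
    for i, p in enumerate(pts):
        if skel[p]:
            out.append(p)
            continue
        prev = pts[i - 1]
        nxt = pts[(i + 1) % n]
        replaced = False
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)):
            q = (p[0] + dr, p[1] + dc)
            if (
                0 <= q[0] < skel.shape[0]
                and 0 <= q[1] < skel.shape[1]
                and skel[q]
                and q not in taken
                and _adj8(q, prev)
                and _adj8(q, nxt)
            ):
                out.append(q)
                taken.add(q)
                replaced = True
                break
        if not replaced:
            if _adj8(prev, nxt) and prev != nxt:
                continue  # drop: neighbors already connect
            out.append(p)
    return np.array(out, dtype=int) if out else path


def extract_cell_outlines(
    skeleton: JunctionSkeleton,
    image_id: str = "",
    min_path_pixels: int = 20,
    border_margin: int = 0,
) -> list[CellOutline]:
    """Trace each enclosed face of the junction skeleton as one cell outline.

    Faces are 4-connected background regions of the skeleton; the outline of
    a face is the ring of skeleton pixels hugging it, traced as a closed
    clockwise loop. Faces that touch the image frame — or come within
    ``border_margin`` pixels of it, where the filter chain's spatial support
    extends beyond the image and junction geometry is unreliable — are
    flagged ``touches_border`` and excluded from scoring downstream. Loops
    shorter than ``min_path_pixels`` are discarded as noise.
    """
    skel = np.asarray(skeleton.skeleton_mask, dtype=bool)
    faces, n_faces = ndi.label(~skel, structure=ndi.generate_binary_structure(2, 1))
    h, w = skel.shape
    outlines: list[CellOutline] = []
    slices = ndi.find_objects(faces)
    for face_id in range(1, n_faces + 1):
        sl = slices[face_id - 1]
        r0 = max(sl[0].start - 2, 0)
        c0 = max(sl[1].start - 2, 0)
        r1 = min(sl[0].stop + 2, h)
        c1 = min(sl[1].stop + 2, w)
        face = faces[r0:r1, c0:c1] == face_id
        ring = ndi.binary_dilation(face, structure=_SQUARE3)
        path = _moore_trace(ring)
        if len(path) < min_path_pixels:
            continue
        path = path + np.array([r0, c0])
        path = _snap_path_to_skeleton(path, skel)
        if len(path) < min_path_pixels:
            continue
        rmin, cmin = path.min(axis=0)
        rmax, cmax = path.max(axis=0)
        face_on_frame = (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == h or sl[1].stop == w
        )
        touches = face_on_frame or (
            rmin < border_margin
            or cmin < border_margin
            or rmax >= h - border_margin
            or cmax >= w - border_margin
        )
        outlines.append(
            CellOutline(cell_id=face_id, path=path, image_id=image_id, touches_border=touches)
        )
    return outlines


def select_outlines(
    outlines: list[CellOutline], k: int = 25, rng_seed: int = 0
) -> list[CellOutline]:
    """Uniform random sample of ``k`` non-border outlines, without replacement.

    Mirrors the experimental design of scoring a fixed number of randomly
    chosen cells per image. If fewer than ``k`` are eligible, all are
    returned and a warning is recorded. Deterministic given ``rng_seed``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    eligible = sorted(
        (o for o in outlines if not o.touches_border), key=lambda o: o.cell_id
    )
    if len(eligible) <= k:
        if len(eligible) < k:
            warnings.warn(
                f"only {len(eligible)} eligible outlines available, requested {k}; "
                "returning all",
                stacklevel=2,
            )
        return eligible
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# the full outline-extraction chain

def trace_outlines(
    img: ImageChannel,
    rolling_radius: int = 20,
    blur_sigma: float = 2.0,
    blur_passes: int = 2,
    dilate_iterations: int = 2,
    bridge_max: int = 10,
    prune_length: int = 5,
    border_margin: int = 20,
    background_subtracted: ImageChannel | None = None,
) -> tuple[JunctionSkeleton, list[CellOutline]]:
    """Run the fixed operator chain from raw channel to cell outlines.

    ``background_subtracted`` lets a caller that already computed the
    rolling-ball step (it is shared with the scoring track) pass it in.
    """
    provenance = []
    if background_subtracted is None:
        background_subtracted = subtract_background(img, radius=rolling_radius)
    provenance.append(f"subtract_background(radius={rolling_radius})")
    blurred = gaussian_blur(background_subtracted, sigma=blur_sigma, passes=blur_passes)
    provenance.append(f"gaussian_blur(sigma={blur_sigma}, passes={blur_passes})")
    sharp = sharpen(blurred)
    provenance.append("sharpen()")
    t = huang_threshold(sharp)
    mask = binarize(sharp, t)
    provenance.append(f"huang_threshold -> {t}; binarize(>{t})")
    mask = dilate_binary(mask, iterations=dilate_iterations)
    provenance.append(f"dilate_binary(iterations={dilate_iterations})")
    mask = close_gaps(mask, max_bridge=bridge_max)
    provenance.append(f"close_gaps(max_bridge={bridge_max})")
    skeleton = skeletonize(mask, prune_length=prune_length)
    skeleton.provenance = provenance + skeleton.provenance
    outlines = extract_cell_outlines(
        skeleton, image_id=img.image_id, border_margin=border_margin
    )
    return skeleton, outlines
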
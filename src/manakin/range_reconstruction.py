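"""Ancestral geographic-range reconstruction under Brownian motion.

Each extant range polygon is summarised by 12 boundary index points (the
four lat/lon extrema plus the eight outermost intersections of the
boundary with the midlines and diagonals of the bounding rectangle).
Every index point is treated as an independent continuous character,
embedded on the unit sphere, and evolved along the ultrametric phylogeny
under Brownian motion (BM).  A Metropolis-Hastings MCMC samples ancestral
node states and the diffusion rate; posterior draws of all 12 points are
re-assembled into credible range polygons per ancestor, and pairwise
ancestral overlap (area of intersection over the smaller range) is scored
draw-wise to classify sympatry.
"""

from __future__ import annotations

import logging
import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import nearest_points
from shapely.validation import make_valid

from .io_formats import GeometryError, Phylogeny, RangePolygon, ValidationError

__all__ = [
    "INDEX_LABELS",
    "IndexPointSet",
    "extract_index_points",
    "geo_to_cartesian",
    "cartesian_to_geo",
    "MCMCSettings",
    "NodePosterior",
    "bm_mcmc",
    "CredibleRange",
    "assemble_posterior_ranges",
    "posterior_polygon_draws",
    "percent_overlap",
    "OverlapResult",
    "overlap_posterior",
    "RangeReconstruction",
    "reconstruct_ranges",
]

logger = logging.getLogger(__name__)

#: fixed order of the 12 index points (also the tie-break order when
#: assembling polygons): 4 extrema interleaved with the 8 ray points.
INDEX_LABELS = (
    "max_lat", "ne", "max_lon", "se", "min_lat", "sw", "min_lon", "nw",
    "n", "e", "s", "w",
)

_RAY_LABELS = ("n", "ne", "e", "se", "s", "sw", "w", "nw")


# ---------------------------------------------------------------------------
# Index points
# ---------------------------------------------------------------------------


@dataclass
class IndexPointSet:
    """The 12 labeled boundary points summarising one range polygon."""

    points: dict[str, tuple[float, float]]   # label -> (lon, lat)
    name: str = ""

    def __post_init__(self) -> None:
        missing = [l for l in INDEX_LABELS if l not in self.points]
        if missing:
            raise ValidationError(f"index point set missing labels {missing}")

    def as_array(self) -> np.ndarray:
        """12 x 2 array of (lon, lat) in the fixed label order."""
        return np.array([self.points[l] for l in INDEX_LABELS], dtype=float)


def _boundary_extreme(boundary, axis: int, value: float):
    """Representative boundary point attaining an extreme coordinate.

    When a whole edge sits at the extreme (e.g. the top edge of a square)
    the midpoint of that edge is returned.
    """
    minx, miny, maxx, maxy = boundary.bounds
    pad = max(maxx - minx, maxy - miny, 1.0)
    if axis == 1:  # latitude extreme -> horizontal cut
        cut = LineString([(minx - pad, value), (maxx + pad, value)])
    else:
        cut = LineString([(value, miny - pad), (value, maxy + pad)])
    inter = boundary.intersection(cut)
    if inter.is_empty:  # numerically grazing: snap to nearest boundary point
        p = nearest_points(cut, boundary)[1]
    else:
        p = nearest_points(inter.centroid, boundary)[1]
    return float(p.x), float(p.y)


def _ray_point(boundary, center: tuple[float, float], direction: tuple[float, float]):
    """Outermost intersection of the ray from *center* with the boundary."""
    cx, cy = center
    dx, dy = direction
    norm = math.hypot(dx, dy)
    dx, dy = dx / norm, dy / norm
    minx, miny, maxx, maxy = boundary.bounds
    reach = 2.0 * math.hypot(maxx - minx, maxy - miny) + 1e-9
    ray = LineString([(cx, cy), (cx + dx * reach, cy + dy * reach)])
    inter = ray.intersection(boundary)
    candidates: list[tuple[float, float]] = []
    geoms = getattr(inter, "geoms", [inter]) if not inter.is_empty else []
    for g in geoms:
        if isinstance(g, Point):
            candidates.append((g.x, g.y))
        else:  # collinear overlap: keep its endpoints
            candidates.extend((x, y) for x, y in g.coords)
    if not candidates:
        p = nearest_points(ray, boundary)[1]
        warnings.warn(
            "ray from bounding-box center missed the polygon boundary; "
            "using nearest boundary point", stacklevel=3,
        )
        return float(p.x), float(p.y)
    # outermost crossing; ties broken by encounter order (stable max)
    best = max(candidates, key=lambda p: math.hypot(p[0] - cx, p[1] - cy))
    return float(best[0]), float(best[1])


def extract_index_points(rp: RangePolygon) -> IndexPointSet:
    """Extract the 12 index points of a range polygon.

    The four extrema attain the polygon's bounding-box extremes; the eight
    ray points are the outermost intersections of the boundary with rays
    from the bounding-rectangle center along its midlines (N/E/S/W) and
    diagonals (NE/SE/SW/NW).  Coincident points are allowed (a square's
    midline points coincide with its edge-midpoint extrema).
    """
    if rp.area <= 0:
        raise GeometryError(f"range {rp.name!r}: degenerate (zero-area) polygon")
    boundary = rp.geom.boundary
    minx, miny, maxx, maxy = rp.bounds
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    hx, hy = (maxx - minx) / 2.0, (maxy - miny) / 2.0
    if hx == 0 or hy == 0:
        raise GeometryError(f"range {rp.name!r}: degenerate bounding box")
    pts: dict[str, tuple[float, float]] = {
        "max_lat": _boundary_extreme(boundary, 1, maxy),
        "min_lat": _boundary_extreme(boundary, 1, miny),
        "max_lon": _boundary_extreme(boundary, 0, maxx),
        "min_lon": _boundary_extreme(boundary, 0, minx),
    }
    # midline directions are axis-aligned; diagonal directions follow the
    # bounding rectangle's diagonals (45° only if the box is square)
    directions = {
        "n": (0.0, 1.0), "s": (0.0, -1.0), "e": (1.0, 0.0), "w": (-1.0, 0.0),
        "ne": (hx, hy), "se": (hx, -hy), "sw": (-hx, -hy), "nw": (-hx, hy),
    }
    for label in _RAY_LABELS:
        pts[label] = _ray_point(boundary, (cx, cy), directions[label])
    return IndexPointSet(points=pts, name=rp.name)


# ---------------------------------------------------------------------------
# Working coordinates: unit-sphere embedding
# ---------------------------------------------------------------------------


def geo_to_cartesian(lonlat: np.ndarray) -> np.ndarray:
    """Embed lon/lat degrees as 3-D unit-sphere Cartesian coordinates.

    (0°, 0°) maps to (1, 0, 0).  This working space avoids longitude
    wrap-around pathologies when modeling BM on geographic points.
    """
    ll = np.asarray(lonlat, dtype=float)
    lon, lat = ll[..., 0], ll[..., 1]
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValidationError("coordinates outside lon [-180,180] / lat [-90,90]")
    lam, phi = np.radians(lon), np.radians(lat)
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)],
        axis=-1,
    )


def cartesian_to_geo(xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`geo_to_cartesian` (points off the sphere are
    normalised back onto it first)."""
    p = np.asarray(xyz, dtype=float)
    norm = np.linalg.norm(p, axis=-1, keepdims=True)
    if np.any(norm <= 0):
        raise ValidationError("cannot project the origin back to lon/lat")
    p = p / norm
    lat = np.degrees(np.arcsin(np.clip(p[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(p[..., 1], p[..., 0]))
    return np.stack([lon, lat], axis=-1)


# ---------------------------------------------------------------------------
# Brownian-motion MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings; defaults give (1e6 - 1e5)/1e4 = 90 retained samples."""

    chain_length: int = 1_000_000
    burn_in: int = 100_000
    thin: int = 10_000
    target_acceptance: tuple[float, float] = (0.30, 0.36)
    initial_step: float = 0.01
    sigma2_step: float = 0.4
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.chain_length <= self.burn_in:
            raise ValidationError("chain_length must exceed burn_in")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.initial_step <= 0 or self.sigma2_step <= 0:
            raise ValidationError("proposal step sizes must be positive")

    @property
    def n_samples(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class NodePosterior:
    """Posterior samples for one index point's ancestral states."""

    node_labels: list[str]
    samples: dict[str, np.ndarray]     # label -> (n_samples, d) working coords
    sigma2: np.ndarray                 # (n_samples,)
    acceptance_rate: float
    settings: MCMCSettings
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.sigma2)

    def lonlat_samples(self, node: str) -> np.ndarray:
        """Posterior draws of a node mapped back to (lon, lat) degrees."""
        s = self.samples[node]
        if s.shape[1] != 3:
            raise ValidationError("lonlat_samples requires 3-D working coordinates")
        return cartesian_to_geo(s)


def bm_mcmc(
    tree: Phylogeny,
    tip_states: Mapping[str, Sequence[float]],
    settings: MCMCSettings | None = None,
    seed: int = 0,
    sigma2: float | None = None,
) -> NodePosterior:
    """Sample ancestral node states under BM by Metropolis-Hastings.

    One chain generation is a full sweep: a Gaussian block proposal on each
    internal node's coordinates followed by a log-normal proposal on the
    diffusion rate sigma^2 (improper uniform prior on log sigma^2).  Step
    sizes are adapted during burn-in only, targeting 30-36% acceptance, and
    frozen afterwards.  Fixing ``sigma2`` disables the rate update (used by
    the closed-form oracle comparisons).

    The BM likelihood factorises over branches: along a branch of length t
    each coordinate changes by N(0, sigma^2 t), independently per
    coordinate.  The log-likelihood therefore only enters through
    S = sum_edges ||x_child - x_parent||^2 / t, which the sampler maintains
    incrementally — node updates touch only adjacent edges and the rate
    update is O(1).
    """
    settings = settings or MCMCSettings()
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValidationError(f"tip states missing for {missing}")
    first = np.atleast_1d(np.asarray(tip_states[tree.tip_labels[0]], dtype=float))
    d = first.size
    n = tree.n_nodes
    internal = [i for i in range(n) if not tree.is_tip[i]]
    internal_set = set(internal)

    # plain-python state for a tight inner loop
    x: list[list[float]] = [[0.0] * d for _ in range(n)]
    tip_mean = [0.0] * d
    n_tips = 0
    for i in range(n):
        if tree.is_tip[i]:
            v = np.atleast_1d(np.asarray(tip_states[tree.labels[i]], dtype=float))
            if v.size != d:
                raise ValidationError("inconsistent tip state dimensions")
            x[i] = [float(z) for z in v]
            for k in range(d):
                tip_mean[k] += x[i][k]
            n_tips += 1
    tip_mean = [v / n_tips for v in tip_mean]
    for i in internal:
        x[i] = list(tip_mean)

    edges = tree.edges()
    if any(t <= 0 for _, _, t in edges):
        # zero-length branches make the BM transition degenerate
        raise ValidationError("bm_mcmc requires strictly positive branch lengths")
    inv_t = [1.0 / t for _, _, t in edges]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]  # node -> (other, 1/t)
    for (p, c, t), it in zip(edges, inv_t):
        adj[p].append((c, it))
        adj[c].append((p, it))

    def edge_ss(a: int, b: int, it: float) -> float:
        xa, xb = x[a], x[b]
        return it * sum((xa[k] - xb[k]) ** 2 for k in range(d))

    S = sum(edge_ss(p, c, it) for (p, c, _), it in zip(edges, inv_t))
    D = d * len(edges)

    sample_rate = sigma2 is None
    if sample_rate:
        # crude scale from tip dispersion over tree depth
        depth = float(tree.depths()[np.asarray(tree.is_tip)].max())
        spread = max(
            sum(
                (x[i][k] - tip_mean[k]) ** 2
                for i in range(n) if tree.is_tip[i] for k in range(d)
            ) / max(n_tips * d - 1, 1),
            1e-12,
        )
        s2 = spread / depth
    else:
        if sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        s2 = float(sigma2)
    u = math.log(s2)

    rng = random.Random(seed)
    gauss = rng.gauss
    uniform = rng.random
    exp, log = math.exp, math.log

    blocks = list(internal) + ([-1] if sample_rate else [])
    step = {b: (settings.initial_step if b >= 0 else settings.sigma2_step)
            for b in blocks}
    acc = {b: 0 for b in blocks}
    prop = {b: 0 for b in blocks}
    post_acc = post_prop = 0

    n_keep = settings.n_samples
    keep: dict[int, list[list[float]]] = {i: [] for i in internal}
    keep_s2: list[float] = []

    lo, hi = settings.target_acceptance
    target = 0.5 * (lo + hi)
    adapt_every = settings.adapt_interval

    for gen in range(1, settings.chain_length + 1):
        in_burn = gen <= settings.burn_in
        for i in internal:
            st = step[i]
            xi = x[i]
            old = list(xi)
            old_ss = 0.0
            for j, it in adj[i]:
                old_ss += edge_ss(i, j, it)
            for k in range(d):
                xi[k] = old[k] + st * gauss(0.0, 1.0)
            new_ss = 0.0
            for j, it in adj[i]:
                new_ss += edge_ss(i, j, it)
            dS = new_ss - old_ss
            prop[i] += 1
            if dS <= 0.0 or uniform() < exp(-0.5 * dS / s2):
                S += dS
                acc[i] += 1
                if not in_burn:
                    post_acc += 1
            else:
                x[i] = old
            if not in_burn:
                post_prop += 1
        if sample_rate:
            u_new = u + step[-1] * gauss(0.0, 1.0)
            dlp = -0.5 * S * (exp(-u_new) - exp(-u)) - 0.5 * D * (u_new - u)
            prop[-1] += 1
            if dlp >= 0.0 or uniform() < exp(dlp):
                u = u_new
                s2 = exp(u)
                acc[-1] += 1
                if not in_burn:
                    post_acc += 1
            if not in_burn:
                post_prop += 1
        if in_burn and gen % adapt_every == 0:
            for b in blocks:
                if prop[b]:
                    rate = acc[b] / prop[b]
                    step[b] *= exp(0.8 * (rate - target))
                    acc[b] = prop[b] = 0
        if not in_burn and (gen - settings.burn_in) % settings.thin == 0:
            if len(keep_s2) < n_keep:
                for i in internal:
                    keep[i].append(list(x[i]))
                keep_s2.append(s2)

    acceptance = post_acc / post_prop if post_prop else float("nan")
    labels = [tree.labels[i] for i in internal]
    return NodePosterior(
        node_labels=labels,
        samples={tree.labels[i]: np.asarray(keep[i], dtype=float) for i in internal},
        sigma2=np.asarray(keep_s2, dtype=float),
        acceptance_rate=acceptance,
        settings=settings,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Posterior range assembly
# ---------------------------------------------------------------------------


@dataclass
class CredibleRange:
    """Point-estimate and 5th/95th-percentile extent polygons for one node."""

    node: str
    point_polygon: RangePolygon
    min_polygon: RangePolygon
    max_polygon: RangePolygon
    median_points: dict[str, tuple[float, float]]
    envelopes: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    order: list[str]


def _ordered_labels(median_pts: np.ndarray) -> list[int]:
    """Assembly order: angle around the centroid, fixed label order on ties."""
    c = median_pts.mean(axis=0)
    ang = np.arctan2(median_pts[:, 1] - c[1], median_pts[:, 0] - c[0])
    return list(np.lexsort((np.arange(len(median_pts)), ang)))


def _simple_polygon(coords: np.ndarray, context: str) -> Polygon:
    poly = Polygon(coords)
    if not poly.is_valid:
        logger.info("repairing self-intersecting polygon (%s)", context)
        fixed = make_valid(poly)
        if fixed.geom_type == "MultiPolygon":
            fixed = max(fixed.geoms, key=lambda g: g.area)
        elif fixed.geom_type == "GeometryCollection":
            polys = [g for g in fixed.geoms if g.geom_type == "Polygon"]
            if not polys:
                raise GeometryError(f"could not repair polygon ({context})")
            fixed = max(polys, key=lambda g: g.area)
        poly = fixed
    return poly


def assemble_posterior_ranges(
    per_point: Mapping[str, NodePosterior],
) -> dict[str, CredibleRange]:
    """Combine the 12 per-index-point posteriors into credible polygons.

    For each internal node the per-point posterior medians (lon/lat) give
    the point-estimate polygon.  The minimum/maximum-extent polygons move
    each point to the 5th/95th percentile of its signed radial coordinate
    (relative to the median-polygon centroid), i.e. toward/away from the
    centre of the reconstructed range.
    """
    missing = [l for l in INDEX_LABELS if l not in per_point]
    if missing:
        raise ValidationError(f"posteriors missing for index points {missing}")
    nodes = per_point[INDEX_LABELS[0]].node_labels
    n_samp = per_point[INDEX_LABELS[0]].n_samples
    for l in INDEX_LABELS:
        if per_point[l].node_labels != nodes or per_point[l].n_samples != n_samp:
            raise ValidationError(
                f"index point {l!r}: mismatched node set or sample count"
            )
    out: dict[str, CredibleRange] = {}
    for node in nodes:
        draws = np.stack(
            [per_point[l].lonlat_samples(node) for l in INDEX_LABELS], axis=1
        )  # (n_samp, 12, 2)
        med = np.median(draws, axis=0)            # (12, 2)
        c = med.mean(axis=0)
        u = med - c
        norms = np.linalg.norm(u, axis=1)
        norms[norms == 0] = 1.0
        u = u / norms[:, None]
        radial = np.einsum("sjk,jk->sj", draws - c, u)   # (n_samp, 12)
        r05 = np.percentile(radial, 5, axis=0)
        r95 = np.percentile(radial, 95, axis=0)
        min_pts = c + r05[:, None] * u
        max_pts = c + r95[:, None] * u
        order = _ordered_labels(med)
        labels_sorted = [INDEX_LABELS[i] for i in order]
        p_point = _simple_polygon(med[order], f"{node}/point")
        p_min = _simple_polygon(min_pts[order], f"{node}/min")
        p_max = _simple_polygon(max_pts[order], f"{node}/max")
        if not p_max.buffer(1e-9).contains(p_min):
            logger.info("clipping min-extent polygon to max extent (%s)", node)
            clipped = p_min.intersection(p_max)
            if clipped.geom_type == "MultiPolygon":
                clipped = max(clipped.geoms, key=lambda g: g.area)
            p_min = clipped
        out[node] = CredibleRange(
            node=node,
            point_polygon=RangePolygon(p_point, name=f"{node}:point"),
            min_polygon=RangePolygon(p_min, name=f"{node}:min"),
            max_polygon=RangePolygon(p_max, name=f"{node}:max"),
            median_points={l: tuple(med[INDEX_LABELS.index(l)]) for l in INDEX_LABELS},
            envelopes={
                l: (tuple(min_pts[INDEX_LABELS.index(l)]),
                    tuple(max_pts[INDEX_LABELS.index(l)]))
                for l in INDEX_LABELS
            },
            order=labels_sorted,
        )
    return out


def posterior_polygon_draws(
    per_point: Mapping[str, NodePosterior], node: str
) -> list[Polygon]:
    """One simple polygon per retained posterior draw for *node*.

    All draws use the assembly order derived from the posterior medians so
    that matched draws across nodes are directly comparable.
    """
    draws = np.stack(
        [per_point[l].lonlat_samples(node) for l in INDEX_LABELS], axis=1
    )
    med = np.median(draws, axis=0)
    order = _ordered_labels(med)
    return [
        _simple_polygon(draws[i][order], f"{node}/draw{i}")
        for i in range(draws.shape[0])
    ]


# ---------------------------------------------------------------------------
# Overlap / sympatry
# ---------------------------------------------------------------------------


def percent_overlap(a: RangePolygon | Polygon, b: RangePolygon | Polygon) -> float:
    """100 * area(a ∩ b) / min(area(a), area(b)); symmetric, in [0, 100]."""
    ga = a.geom if isinstance(a, RangePolygon) else a
    gb = b.geom if isinstance(b, RangePolygon) else b
    smaller = min(ga.area, gb.area)
    if smaller <= 0:
        raise GeometryError("percent_overlap requires positive-area polygons")
    pct = 100.0 * ga.intersection(gb).area / smaller
    return float(min(max(pct, 0.0), 100.0))


@dataclass
class OverlapResult:
    """Posterior percent overlap between two reconstructed ranges."""

    pair: tuple[str, str]
    median: float
    lo: float            # 5th percentile
    hi: float            # 95th percentile
    threshold: float
    sympatric: bool
    n_draws: int
    draws: np.ndarray = field(repr=False)


def overlap_posterior(
    per_point: Mapping[str, NodePosterior],
    node_a: str,
    node_b: str,
    threshold: float = 0.25,
) -> OverlapResult:
    """Draw-wise percent overlap between two nodes' posterior ranges.

    Overlap is computed between matched draws (draw i of node a against
    draw i of node b), giving a posterior distribution of percent overlap.
    Sympatry is called when the median overlap is at least ``threshold``
    (a fraction; 0.25 by default, configurable down to 0.20).
    """
    if not 0 < threshold <= 1:
        raise ValidationError("sympatry threshold must be a fraction in (0, 1]")
    polys_a = posterior_polygon_draws(per_point, node_a)
    polys_b = posterior_polygon_draws(per_point, node_b)
    if len(polys_a) != len(polys_b):
        raise ValidationError("sample-count mismatch between node posteriors")
    draws = np.array([percent_overlap(pa, pb) for pa, pb in zip(polys_a, polys_b)])
    median = float(np.median(draws))
    lo, hi = (float(v) for v in np.percentile(draws, [5, 95]))
    return OverlapResult(
        pair=(node_a, node_b),
        median=median, lo=lo, hi=hi,
        threshold=threshold,
        sympatric=median >= 100.0 * threshold,
        n_draws=len(draws),
        draws=draws,
    )


# ---------------------------------------------------------------------------
# End-to-end reconstruction
# ---------------------------------------------------------------------------


@dataclass
class RangeReconstruction:
    """Everything the range stage produces."""

    tree: Phylogeny
    index_points: dict[str, IndexPointSet]          # species -> points
    posteriors: dict[str, NodePosterior]            # index label -> posterior
    credible_ranges: dict[str, CredibleRange]       # node -> polygons
    overlaps: list[OverlapResult]
    seed: int


def _spawn_seed(seed: int, i: int) -> int:
    return (seed * 1_000_003 + 7919 * (i + 1)) % (2**31 - 1)


def reconstruct_ranges(
    tree: Phylogeny,
    ranges: Mapping[str, RangePolygon],
    settings: MCMCSettings | None = None,
    seed: int = 0,
    threshold: float = 0.25,
    node_pairs: Iterable[tuple[str, str]] | None = None,
) -> RangeReconstruction:
    """Run the full ancestral-range reconstruction.

    ``ranges`` maps tip labels to extant range polygons.  One MCMC chain is
    run per index point (12 chains), each on the 3-D sphere embedding of
    that point across species.  Overlap is scored for every internal node
    pair unless ``node_pairs`` restricts it.
    """
    settings = settings or MCMCSettings()
    missing = [t for t in tree.tip_labels if t not in ranges]
    if missing:
        raise ValidationError(f"no range polygon for tip(s) {missing}")
    ipoints = {sp: extract_index_points(ranges[sp]) for sp in tree.tip_labels}
    posteriors: dict[str, NodePosterior] = {}
    for i, label in enumerate(INDEX_LABELS):
        tip_states = {
            sp: geo_to_cartesian(np.array(ipoints[sp].points[label]))
            for sp in tree.tip_labels
        }
        posteriors[label] = bm_mcmc(
            tree, tip_states, settings=settings, seed=_spawn_seed(seed, i)
        )
        logger.info(
            "index point %-7s acceptance %.3f", label, posteriors[label].acceptance_rate
        )
    credible = assemble_posterior_ranges(posteriors)
    internal = tree.internal_labels
    if node_pairs is None:
        node_pairs = [
            (internal[i], internal[j])
            for i in range(len(internal)) for j in range(i + 1, len(internal))
        ]
    overlaps = [
        overlap_posterior(posteriors, a, b, threshold=threshold)
        for a, b in node_pairs
    ]
    return RangeReconstruction(
        tree=tree, index_points=ipoints, posteriors=posteriors,
        credible_ranges=credible, overlaps=overlaps, seed=seed,
    )
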
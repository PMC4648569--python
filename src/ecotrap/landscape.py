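"""Grid landscape: host/aridity rasters, patch metrics, phenology, map generators.

The habitat is a rectangular grid of 0.25 m × 0.25 m cells.  Each cell carries
one host-plant code (one of four native crucifers, the non-native *Thlaspi
arvense*, or none) and one aridity class (wet / intermediate / dry).  Patches
are 4-connected components of same-species cells; the six spatial attributes
of the non-native distribution (cover, patchnum, area, shape, dist, thdist)
are computed from them.  Scenario generators rebuild the non-native layer
under controlled spatial attributes while leaving the native layer untouched
(except where patch enlargement overwrites it).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path as _Path

import numpy as np
from scipy import ndimage

CELL_SIZE = 0.25  # m
CELL_AREA = CELL_SIZE * CELL_SIZE  # m^2

#: 4-connectivity structuring element (edge-sharing adjacency).
_N4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class Species(IntEnum):
    """Per-cell host codes (0 means no host plant in the cell)."""

    NONE = 0
    BOECHERA = 1
    CARDAMINE = 2
    DRABA = 3
    DESCURAINIA = 4
    THLASPI = 5


class Aridity(IntEnum):
    WET = 0
    INTERMEDIATE = 1
    DRY = 2


NATIVE_SPECIES = (
    Species.BOECHERA,
    Species.CARDAMINE,
    Species.DRABA,
    Species.DESCURAINIA,
)
HOST_SPECIES = NATIVE_SPECIES + (Species.THLASPI,)


class MapFormatError(ValueError):
    """Raised when a map file cannot be parsed; carries the offending line."""

    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class GridMap:
    """Cell-level landscape: a host-species layer and an aridity layer.

    Both layers are integer rasters of shape ``(n_rows, n_cols)``; row 0 is
    the southern (lower) edge of the habitat, and a continuous position
    ``(x, y)`` in metres maps to cell ``(floor(y/0.25), floor(x/0.25))``.
    """

    host: np.ndarray
    aridity: np.ndarray
    cell_size: float = CELL_SIZE

    def __post_init__(self):
        self.host = np.asarray(self.host, dtype=np.int8)
        self.aridity = np.asarray(self.aridity, dtype=np.int8)
        if self.host.ndim != 2 or self.host.shape != self.aridity.shape:
            raise ValueError("host and aridity layers must be 2-D and congruent")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.host.min() < 0 or self.host.max() > max(Species):
            raise ValueError("unknown species code in host layer")
        if self.aridity.min() < 0 or self.aridity.max() > max(Aridity):
            raise ValueError("unknown aridity code in aridity layer")

    @property
    def n_rows(self) -> int:
        return self.host.shape[0]

    @property
    def n_cols(self) -> int:
        return self.host.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the habitat in metres."""
        return self.n_cols * self.cell_size, self.n_rows * self.cell_size

    @property
    def habitat_area_ha(self) -> float:
        return self.n_rows * self.n_cols * self.cell_size**2 / 1e4

    def mask(self, species) -> np.ndarray:
        return self.host == int(species)

    @property
    def native_mask(self) -> np.ndarray:
        return (self.host >= Species.BOECHERA) & (self.host <= Species.DESCURAINIA)

    @property
    def host_mask(self) -> np.ndarray:
        return self.host != Species.NONE

    @property
    def thlaspi_mask(self) -> np.ndarray:
        return self.host == Species.THLASPI

    def copy(self) -> "GridMap":
        return GridMap(self.host.copy(), self.aridity.copy(), self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) in metres of the centre of a cell."""
        return (col + 0.5) * self.cell_size, (row + 0.5) * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        r = min(max(int(y // self.cell_size), 0), self.n_rows - 1)
        c = min(max(int(x // self.cell_size), 0), self.n_cols - 1)
        return r, c


# ---------------------------------------------------------------------------
# Map file I/O (canonical ASCII-grid dialect, bit-exact round trip)
# ---------------------------------------------------------------------------

def write_map(gmap: GridMap, path) -> None:
    """Write the canonical ASCII dialect: header, then [HOST] and [ARIDITY]."""
    lines = [
        f"ncols {gmap.n_cols}",
        f"nrows {gmap.n_rows}",
        f"cellsize {gmap.cell_size:g}",
        "nodata -1",
        "[HOST]",
    ]
    lines += [" ".join(str(v) for v in row) for row in gmap.host]
    lines.append("[ARIDITY]")
    lines += [" ".join(str(v) for v in row) for row in gmap.aridity]
    _Path(path).write_text("\n".join(lines) + "\n")


def read_map(path) -> GridMap:
    """Read a map file written in the canonical ASCII dialect.

    Raises :class:`MapFormatError` (naming the line number) on malformed
    headers, unknown codes, or inconsistent row lengths.
    """
    text = _Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    for key in ("ncols", "nrows", "cellsize", "nodata"):
        if i >= len(lines):
            raise MapFormatError(f"missing header line '{key}'", i + 1)
        parts = lines[i].split()
        if len(parts) != 2 or parts[0] != key:
            raise MapFormatError(f"expected header '{key} <value>', got {lines[i]!r}", i + 1)
        try:
            header[key] = float(parts[1])
        except ValueError:
            raise MapFormatError(f"non-numeric value for '{key}'", i + 1) from None
        i += 1
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if n_cols <= 0 or n_rows <= 0:
        raise MapFormatError("ncols and nrows must be positive", 1)

    def read_block(tag, i, lo, hi):
        if i >= len(lines) or lines[i].strip() != tag:
            raise MapFormatError(f"expected block marker '{tag}'", i + 1)
        i += 1
        rows = []
        for r in range(n_rows):
            if i >= len(lines):
                raise MapFormatError(f"unexpected end of file inside {tag}", i + 1)
            vals = lines[i].split()
            if len(vals) != n_cols:
                raise MapFormatError(
                    f"{tag} row has {len(vals)} values, expected {n_cols}", i + 1
                )
            try:
                row = [int(v) for v in vals]
            except ValueError:
                raise MapFormatError(f"non-integer code in {tag}", i + 1) from None
            for v in row:
                if not (lo <= v <= hi):
                    raise MapFormatError(f"unknown code {v} in {tag}", i + 1)
            rows.append(row)
            i += 1
        return np.array(rows, dtype=np.int8), i

    host, i = read_block("[HOST]", i, 0, int(max(Species)))
    aridity, i = read_block("[ARIDITY]", i, 0, int(max(Aridity)))
    return GridMap(host, aridity, cell_size=header["cellsize"])


# ---------------------------------------------------------------------------
# Patches and spatial metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """A 4-connected set of same-species cells.

    ``area`` is in m^2 (|cells| * 0.0625) and ``perimeter`` in metres (number
    of cell edges bordering a different species, no host, or the habitat edge,
    times 0.25).
    """

    species: Species
    cells: frozenset
    area: float
    perimeter: float

    @property
    def shape_index(self) -> float:
        return patch_shape_index(self)

    def cell_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array(sorted(self.cells), dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def boundary_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Cells with at least one 4-neighbour outside the patch."""
        cells = self.cells
        rows, cols = [], []
        for r, c in cells:
            if (
                (r - 1, c) not in cells
                or (r + 1, c) not in cells
                or (r, c - 1) not in cells
                or (r, c + 1) not in cells
            ):
                rows.append(r)
                cols.append(c)
        return np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64)


def _patch_from_mask(mask: np.ndarray, species: Species, offset=(0, 0)) -> Patch:
    n_cells = int(mask.sum())
    # internal horizontal + vertical adjacencies
    internal = int((mask[:, :-1] & mask[:, 1:]).sum()) + int((mask[:-1] & mask[1:]).sum())
    perimeter_edges = 4 * n_cells - 2 * internal
    rr, cc = np.nonzero(mask)
    cells = frozenset(zip((rr + offset[0]).tolist(), (cc + offset[1]).tolist()))
    return Patch(
        species=Species(species),
        cells=cells,
        area=n_cells * CELL_AREA,
        perimeter=perimeter_edges * CELL_SIZE,
    )


def identify_patches(gmap: GridMap, species) -> list[Patch]:
    """4-connected components of cells of one species, as :class:`Patch` list."""
    species = Species(species)
    if species == Species.NONE:
        raise ValueError("patches are defined for host species, not empty cells")
    mask = gmap.mask(species)
    labels, n = ndimage.label(mask, structure=_N4)
    patches = []
    for sl, lab in zip(ndimage.find_objects(labels, n), range(1, n + 1)):
        sub = labels[sl] == lab
        patches.append(_patch_from_mask(sub, species, offset=(sl[0].start, sl[1].start)))
    return patches


def patch_shape_index(patch: Patch) -> float:
    """Compactness: 0.25 * perimeter[m] / sqrt(area[m^2]); 1.0 for any square."""
    if not patch.cells:
        raise ValueError("shape index undefined for an empty patch")
    return 0.25 * patch.perimeter / math.sqrt(patch.area)


def _rect_min_dist_m(r1, c1, r2, c2) -> float:
    """Min distance (m) between cell squares of two cell sets (arrays)."""
    dr = np.abs(r1[:, None] - r2[None, :]).astype(np.float64)
    dc = np.abs(c1[:, None] - c2[None, :]).astype(np.float64)
    np.maximum(dr - 1.0, 0.0, out=dr)
    np.maximum(dc - 1.0, 0.0, out=dc)
    d2 = dr * dr + dc * dc
    return float(np.sqrt(d2.min())) * CELL_SIZE


def nearest_periphery_distance(a: Patch, b: Patch) -> float:
    """Least Euclidean distance between the peripheries of two patches.

    Cell peripheries are the boundaries of the 0.25 m squares (continuous
    geometry): orthogonally adjacent patches are 0 m apart.
    """
    if not a.cells or not b.cells:
        raise ValueError("patches must be non-empty")
    if a.cells == b.cells:
        raise ValueError("periphery distance requires two distinct patches")
    if a.cells & b.cells:
        raise ValueError("patches must be disjoint")
    ra, ca = a.boundary_cells()
    rb, cb = b.boundary_cells()
    return _rect_min_dist_m(ra, ca, rb, cb)


def _mask_boundary_cells(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not mask.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_N4, border_value=0)
    rr, cc = np.nonzero(mask & ~interior)
    return rr.astype(np.int64), cc.astype(np.int64)


@dataclass
class SpatialMetrics:
    """The six spatial attributes of the non-native distribution.

    Undefined attributes (e.g. ``thdist`` with fewer than two patches) are NaN.
    """

    cover: float
    patchnum: int
    area: float
    shape: float
    dist: float
    thdist: float

    _FIELDS = ("cover", "patchnum", "area", "shape", "dist", "thdist")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}


def compute_spatial_metrics(gmap: GridMap) -> SpatialMetrics:
    """Cover, patch number, mean patch area/shape, and mean nearest-periphery
    distances of the non-native host to natives (dist) and to itself (thdist).
    """
    n_host = int(gmap.host_mask.sum())
    if n_host == 0:
        raise ValueError("map contains no host cells")
    patches = identify_patches(gmap, Species.THLASPI)
    n_thl = int(gmap.thlaspi_mask.sum())
    cover = n_thl / n_host
    if not patches:
        return SpatialMetrics(0.0, 0, math.nan, math.nan, math.nan, math.nan)

    area = float(np.mean([p.area for p in patches]))
    shape = float(np.mean([p.shape_index for p in patches]))

    nat_r, nat_c = _mask_boundary_cells(gmap.native_mask)
    boundaries = [p.boundary_cells() for p in patches]
    if nat_r.size:
        dist = float(np.mean([_rect_min_dist_m(r, c, nat_r, nat_c) for r, c in boundaries]))
    else:
        dist = math.nan

    if len(patches) >= 2:
        dists = []
        for i, (r, c) in enumerate(boundaries):
            other_r = np.concatenate([boundaries[j][0] for j in range(len(patches)) if j != i])
            other_c = np.concatenate([boundaries[j][1] for j in range(len(patches)) if j != i])
            dists.append(_rect_min_dist_m(r, c, other_r, other_c))
        thdist = float(np.mean(dists))
    else:
        thdist = math.nan
    return SpatialMetrics(cover, len(patches), area, shape, dist, thdist)


def cover_area_ha(total_host_area_ha: float, cover_fraction: float) -> float:
    """Area (ha) of the non-native host at a given cover fraction of the total
    host area — the bookkeeping behind statements like "10% of 1.3 ha is 0.13 ha".
    """
    return total_host_area_ha * cover_fraction


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

def _default_availability() -> dict:
    avail = {}
    for sp in HOST_SPECIES:
        avail[(int(sp), 1)] = True
        avail[(int(sp), 2)] = sp not in (Species.BOECHERA, Species.DESCURAINIA)
        avail[(int(sp), 3)] = sp == Species.CARDAMINE
    return avail


@dataclass
class PhenologyCalendar:
    """Which host species has fresh (usable) leaves in each trimester of the
    54-day flight season.  Defaults: all five species in trimester 1; two of
    the natives senesce in trimester 2; only *Cardamine* remains in trimester 3.
    """

    season_length: int = 54
    availability: dict = field(default_factory=_default_availability)

    def trimester(self, day: int) -> int:
        if not 1 <= day <= self.season_length:
            raise ValueError(f"day {day} outside season 1..{self.season_length}")
        return math.ceil(3 * day / self.season_length)

    def is_available(self, species, trimester: int) -> bool:
        if int(species) == Species.NONE:
            return False
        return bool(self.availability.get((int(species), trimester), False))

    def available_masks(self, gmap: GridMap) -> np.ndarray:
        """(3, n_rows, n_cols) boolean: an available host occupies the cell."""
        out = np.zeros((3,) + gmap.host.shape, dtype=bool)
        for t in range(1, 4):
            for sp in HOST_SPECIES:
                if self.is_available(sp, t):
                    out[t - 1] |= gmap.host == int(sp)
        return out


def host_available(gmap: GridMap, cell, day: int, cal: PhenologyCalendar) -> bool:
    """True iff the cell holds a host species with fresh leaves on that day."""
    species = int(gmap.host[cell[0], cell[1]])
    return cal.is_available(species, cal.trimester(day))


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """A recipe for rebuilding the non-native layer of a map.

    mode: 'squares' | 'elongated' | 'scatter' | 'enlarge'
    cover: target fraction of all host cells occupied by the non-native.
    placement_natives / placement_mutual: 'close' | 'far' | 'base' control
    where new patches go relative to native patches / to each other.
    """

    mode: str
    cover: float
    patch_count: int = 1
    placement_natives: str = "base"
    placement_mutual: str = "base"
    min_spacing: int = 2
    aspect: float = 16.0
    label: str = ""

    def __post_init__(self):
        if self.mode not in ("squares", "elongated", "scatter", "enlarge"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if not 0.0 <= self.cover < 1.0:
            raise ValueError("cover must be in [0, 1)")
        for fieldname in ("placement_natives", "placement_mutual"):
            if getattr(self, fieldname) not in ("close", "far", "base"):
                raise ValueError(f"{fieldname} must be close/far/base")


def _placement_candidates(host, placement_natives, rng):
    """Boolean mask of vacant cells admissible under the native-distance rule."""
    vacant = host == Species.NONE
    native = (host >= Species.BOECHERA) & (host <= Species.DESCURAINIA)
    if placement_natives == "base" or not native.any():
        return vacant
    # distance (in cells, ~centre-to-centre) to the nearest native cell
    dtn = ndimage.distance_transform_edt(~native)
    vals = dtn[vacant]
    if placement_natives == "close":
        band = vacant & (dtn <= max(4.0, np.quantile(vals, 0.10)))
    else:  # far
        band = vacant & (dtn >= np.quantile(vals, 0.70))
    return band if band.any() else vacant


def _apply_mutual(cand: np.ndarray, placed: np.ndarray, placement_mutual: str,
                  scale_cells: float) -> np.ndarray:
    """Restrict candidates relative to already-placed non-native cells."""
    if placement_mutual == "base" or not placed.any():
        return cand
    dtp = ndimage.distance_transform_edt(~placed)
    if placement_mutual == "close":
        band = cand & (dtp <= max(3.0, 2.0 * scale_cells))
    else:
        band = cand & (dtp >= 4.0 * scale_cells)
    return band if band.any() else cand


def _choose_cell(cand_mask, rng):
    rr, cc = np.nonzero(cand_mask)
    k = rng.integers(rr.size)
    return int(rr[k]), int(cc[k])


def _scatter(host, target, spec, rng):
    placed = np.zeros_like(host, dtype=bool)
    forbidden = np.zeros_like(host, dtype=bool)
    cand0 = _placement_candidates(host, spec.placement_natives, rng)
    s = spec.min_spacing
    n_placed = 0
    tries = 0
    while n_placed < target:
        cand = _apply_mutual(cand0 & ~forbidden, placed, spec.placement_mutual,
                             scale_cells=float(s))
        cand &= ~forbidden
        if not cand.any():
            if spec.placement_natives != "base" or spec.placement_mutual != "base":
                # relax the placement band rather than fail outright
                cand0 = host == Species.NONE
                cand = cand0 & ~forbidden
            if not cand.any():
                raise ValueError(
                    f"scatter infeasible: placed {n_placed} of {target} cells"
                )
        r, c = _choose_cell(cand, rng)
        placed[r, c] = True
        r0, r1 = max(r - s + 1, 0), min(r + s, host.shape[0])
        c0, c1 = max(c - s + 1, 0), min(c + s, host.shape[1])
        forbidden[r0:r1, c0:c1] = True
        n_placed += 1
        tries += 1
        if tries > 50 * target + 1000:
            raise ValueError("scatter placement did not converge")
    return placed


def _rect_blocks(host, target, spec, rng, aspect):
    """Place `patch_count` vacant rectangles totalling ~`target` cells."""
    n = spec.patch_count
    per = max(1, int(round(target / n)))
    if aspect <= 1.0:
        side = max(1, int(round(math.sqrt(per))))
        w, h = side, side
    else:
        w = max(1, int(round(math.sqrt(per / aspect))))
        h = max(1, int(round(per / w)))
    placed = np.zeros_like(host, dtype=bool)
    cand0 = _placement_candidates(host, spec.placement_natives, rng)
    footprint = np.ones((h, w), dtype=bool)
    n_rows, n_cols = host.shape
    if h > n_rows or w > n_cols:
        raise ValueError(f"a {h}x{w} patch does not fit the {n_rows}x{n_cols} habitat")
    for i in range(n):
        # valid top-left corners: footprint entirely vacant, inside the band,
        # and not touching already-placed non-native cells (integral image)
        free = ((host == Species.NONE) & ~ndimage.binary_dilation(placed, _N4)).astype(np.int64)
        S = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
        S[1:, 1:] = free.cumsum(0).cumsum(1)
        block = S[h:, w:] - S[:-h, w:] - S[h:, :-w] + S[:-h, :-w]
        corner_ok = np.zeros_like(placed)
        corner_ok[: n_rows - h + 1, : n_cols - w + 1] = block == h * w
        cand = corner_ok & cand0
        cand = _apply_mutual(cand, placed, spec.placement_mutual,
                             scale_cells=float(max(h, w)))
        if not cand.any():
            cand = corner_ok
        if not cand.any():
            raise ValueError(
                f"no room for a {h}x{w} patch (placed {i} of {n})"
            )
        r, c = _choose_cell(cand, rng)
        placed[r:r + h, c:c + w] = True
    # trim/extend to hit the target within +-1 where shape allows
    excess = int(placed.sum()) - target
    if excess > 0 and aspect > 1.0:
        # shave cells off the end of the last rectangle (keeps it compact-ish)
        rr, cc = np.nonzero(placed[r:r + h, c:c + w])
        order = np.lexsort((cc, rr))[::-1]
        for k in order[:excess]:
            placed[r + rr[k], c + cc[k]] = False
    return placed


def _enlarge(gmap, target_cover, rng):
    host = gmap.host.copy()
    thl = host == Species.THLASPI
    if not thl.any():
        raise ValueError("enlarge mode requires existing non-native patches")

    n_host_other = int(((host != Species.NONE) & ~thl).sum())

    def cover(n_thl, n_native_eaten):
        return n_thl / (n_thl + n_host_other - n_native_eaten)

    native = gmap.native_mask
    n_thl = int(thl.sum())
    eaten = 0
    if cover(n_thl, eaten) >= target_cover:
        return thl
    while True:
        shell = ndimage.binary_dilation(thl, structure=_N4) & ~thl
        if not shell.any():
            raise ValueError("enlarge: habitat saturated before reaching target cover")
        rr, cc = np.nonzero(shell)
        order = rng.permutation(rr.size)
        for k in order:
            r, c = rr[k], cc[k]
            thl[r, c] = True
            n_thl += 1
            if native[r, c]:
                eaten += 1
            if cover(n_thl, eaten) >= target_cover:
                return thl


def generate_scenario_map(base: GridMap, spec: ScenarioSpec, rng) -> GridMap:
    """Rebuild the non-native layer of `base` according to `spec`.

    Placement modes replace the existing non-native cells entirely; `enlarge`
    dilates the existing patches in place (overwriting natives in conflict,
    which mirrors the construction of the high-cover scenarios).
    """
    rng = np.random.default_rng(rng)
    out = base.copy()
    if spec.mode == "enlarge":
        thl = _enlarge(base, spec.cover, rng)
        out.host[thl] = Species.THLASPI
        return out

    out.host[out.thlaspi_mask] = Species.NONE
    native_count = int(out.native_mask.sum())
    if native_count == 0:
        raise ValueError("scenario base map has no native host cells")
    target = int(round(spec.cover / (1.0 - spec.cover) * native_count))
    if target == 0:
        return out
    vacant = int((out.host == Species.NONE).sum())
    if target > vacant:
        raise ValueError(
            f"infeasible scenario: {target} non-native cells requested, "
            f"{vacant} vacant cells available"
        )
    if spec.mode == "scatter":
        placed = _scatter(out.host, target, spec, rng)
    elif spec.mode == "squares":
        placed = _rect_blocks(out.host, target, spec, rng, aspect=1.0)
    else:  # elongated
        placed = _rect_blocks(out.host, target, spec, rng, aspect=spec.aspect)
    out.host[placed] = Species.THLASPI
    return out


# ---------------------------------------------------------------------------
# Fixture landscape generator
# ---------------------------------------------------------------------------

#: characteristic patch radii in cells; Cardamine forms large dense stands,
#: Draba small scattered ones.
_PATCH_RADIUS = {
    Species.BOECHERA: 7,
    Species.CARDAMINE: 20,
    Species.DRABA: 4,
    Species.DESCURAINIA: 7,
    Species.THLASPI: 5,
}

#: default host-species composition of the fixture landscape (fractions of
#: native host cells).  Together with the corridor geometry below this is the
#: generator's demographic calibration: the published parameterisation is
#: defined by a stationary population (R = 1) in the absence of the
#: non-native host, and with juvenile survival fixed at its published value
#: the stationarity is carried by the landscape's phenology structure — the
#: share of hosts that senesce after the first trimester and the transit
#: distance to the late-season Cardamine refuge.
_DEFAULT_MIX = {
    Species.BOECHERA: 0.37,
    Species.CARDAMINE: 0.21,
    Species.DRABA: 0.05,
    Species.DESCURAINIA: 0.37,
}

#: host species are segregated by moisture: Cardamine forms streamside
#: stands in the wet zone, Boechera/Descurainia sit in intermediate meadows,
#: Draba in the dry zone; the non-native invades disturbed ground anywhere.
_SPECIES_ZONE = {
    Species.CARDAMINE: Aridity.WET,
    Species.BOECHERA: Aridity.INTERMEDIATE,
    Species.DESCURAINIA: Aridity.INTERMEDIATE,
    Species.DRABA: Aridity.DRY,
}


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = rr * rr + cc * cc <= radius * radius
    return rr[keep], cc[keep]


def _stamp_patches(host, species, target_cells, radius, rng, centers=None,
                   max_tries=200_000):
    """Stamp quasi-circular patches of `species` onto vacant cells until
    exactly `target_cells` are occupied (the final stamp is truncated).
    ``centers`` restricts patch centres to a set of (row, col) candidates
    (e.g. the species' aridity zone)."""
    n_rows, n_cols = host.shape
    placed = 0
    tries = 0
    while placed < target_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {target_cells} cells of {species!r}")
        rad = max(1, int(round(radius * rng.lognormal(0.0, 0.35))))
        rad = min(rad, max(n_rows, n_cols) // 3)
        orr, occ = _disk_offsets(rad)
        if centers is None:
            r0 = rng.integers(n_rows)
            c0 = rng.integers(n_cols)
        else:
            r0, c0 = centers[rng.integers(len(centers))]
        rr, cc = orr + r0, occ + c0
        keep = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        rr, cc = rr[keep], cc[keep]
        free = host[rr, cc] == Species.NONE
        rr, cc = rr[free], cc[free]
        if rr.size == 0:
            continue
        take = min(rr.size, target_cells - placed)
        host[rr[:take], cc[:take]] = int(species)
        placed += take


def _aridity_bands(n_rows, n_cols, rng) -> np.ndarray:
    """Block-structured aridity: three roughly vertical zones with jittered
    boundaries (wet near one edge, dry near the other)."""
    aridity = np.empty((n_rows, n_cols), dtype=np.int8)
    b1 = n_cols / 3.0
    b2 = 2.0 * n_cols / 3.0
    # mean-reverting boundary wiggle: blocky, irregular zone edges whose
    # areas stay close to equal thirds from one realisation to the next
    amp = max(1.0, n_cols / 80.0)

    def wiggle():
        x = np.empty(n_rows)
        x[0] = 0.0
        eps = rng.normal(0.0, amp / 4.0, n_rows)
        for r in range(1, n_rows):
            x[r] = 0.9 * x[r - 1] + eps[r]
        return x

    bounds1 = np.clip(b1 + wiggle(), 1, n_cols - 2)
    bounds2 = np.clip(b2 + wiggle(), 2, n_cols - 1)
    cols = np.arange(n_cols)
    for r in range(n_rows):
        lo, hi = sorted((bounds1[r], bounds2[r]))
        aridity[r] = np.where(cols < lo, Aridity.WET,
                              np.where(cols < hi, Aridity.INTERMEDIATE, Aridity.DRY))
    return aridity


def generate_fixture_landscape(
    n_rows: int = 400,
    n_cols: int = 6440,
    host_fraction: float = 1.3 / 16.1,
    thlaspi_cover: float = 0.027,
    species_mix: dict | None = None,
    seed=None,
) -> GridMap:
    """Synthetic stand-in for the observed habitat map.

    Emulates the structure of the field site: a rectangular 16.1 ha habitat
    (by default a 100 m x 1610 m valley-bottom corridor along the moisture
    gradient) with patchy native hosts covering ~8% of the habitat (1.3 ha
    of hosts in 16.1 ha), species segregated by aridity zone, scattered
    small non-native patches making up ``thlaspi_cover`` of all host cells,
    and block-structured aridity zones.  The corridor geometry and the
    species mix are calibrated so that, under the published life-history
    defaults and with no non-native host, the population is stationary
    (R ~ 1), which is how the published parameterisation is defined.
    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if not 0.0 < host_fraction < 1.0:
        raise ValueError("host_fraction must be in (0, 1); a hostless habitat "
                         "cannot support the butterfly population")
    if not 0.0 <= thlaspi_cover < 1.0:
        raise ValueError("thlaspi_cover must be in [0, 1)")
    mix = dict(species_mix or _DEFAULT_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("species_mix fractions must sum to 1")

    n_cells = n_rows * n_cols
    host_target = int(round(host_fraction * n_cells))
    thl_target = int(round(thlaspi_cover * host_target))
    native_target = host_target - thl_target

    aridity = _aridity_bands(n_rows, n_cols, rng)
    host = np.zeros((n_rows, n_cols), dtype=np.int8)
    # largest patches first so later species fill the gaps
    species_order = sorted(mix, key=lambda sp: -_PATCH_RADIUS[Species(sp)])
    targets = {sp: int(round(mix[sp] * native_target)) for sp in mix}
    # rounding drift goes to the most abundant species
    drift = native_target - sum(targets.values())
    targets[max(targets, key=targets.get)] += drift
    scale = min(1.0, math.sqrt(n_cells / 2_576_000))  # shrink stamps on small grids
    zone_centers = {
        a: np.argwhere(aridity == int(a)) for a in Aridity
    }
    # patches are stamped stratified along the corridor (equal share per
    # longitudinal segment) so the host supply is homogeneous along its
    # length rather than clumped by sampling accident
    n_seg = max(1, min(16, n_cols // 40))
    seg_edges = np.linspace(0, n_cols, n_seg + 1)
    for sp in species_order:
        rad = max(2, int(round(_PATCH_RADIUS[Species(sp)] * scale))) if scale < 1 else _PATCH_RADIUS[Species(sp)]
        band = _SPECIES_ZONE.get(Species(sp))
        centers = zone_centers[band] if band is not None else np.argwhere(aridity >= 0)
        shares = np.full(n_seg, targets[sp] // n_seg, dtype=np.int64)
        shares[: targets[sp] % n_seg] += 1
        for k in range(n_seg):
            if shares[k] == 0:
                continue
            in_seg = (centers[:, 1] >= seg_edges[k]) & (centers[:, 1] < seg_edges[k + 1])
            # a segment overlapping only a sliver of the zone cannot hold its
            # share; spill such shares over the whole zone instead
            enough = int(in_seg.sum()) >= 4 * int(shares[k])
            seg_centers = centers[in_seg] if enough else centers
            _stamp_patches(host, sp, int(shares[k]), rad, rng, centers=seg_centers)
    if thl_target:
        rad = max(1, int(round(_PATCH_RADIUS[Species.THLASPI] * scale))) if scale < 1 else _PATCH_RADIUS[Species.THLASPI]
        _stamp_patches(host, Species.THLASPI, thl_target, rad, rng)

    return GridMap(host, aridity)
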
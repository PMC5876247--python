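"""Spherical volume-conductor head model, montage, source space and lead field.

The head is modeled as three concentric spheres of piecewise-homogeneous
conductivity (brain, skull, scalp).  Scalp potentials generated by a current
dipole inside the innermost sphere are obtained from the classical spherical-
harmonic series solution of the quasi-static Poisson problem: for each harmonic
order the radial transfer through the layered conductor is found by solving the
boundary-condition system (continuity of potential and of radial current at the
two internal interfaces, zero radial current at the scalp surface).

All potentials are referenced by subtracting the potential predicted at the
reference position (tip of the nose in the default montage), mirroring a
nose-referenced EEG recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = [
    "HeadModel",
    "Montage",
    "SourceSpace",
    "LeadField",
    "build_head_model",
    "build_montage",
    "build_source_space",
    "compute_lead_field",
    "dipole_potentials",
    "PAPER_CONDUCTIVITIES",
    "DEFAULT_RADII",
]

#: Conductivity triple (S/m) assigned to (brain, scalp, skull).
PAPER_CONDUCTIVITIES = (0.33, 0.022, 0.013)

#: Default shell outer radii in meters: brain, skull, scalp.
DEFAULT_RADII = (0.08, 0.085, 0.092)

DEFAULT_N_TERMS = 60


class ValidationError(ValueError):
    """Raised when a model component violates its construction contract."""


@dataclass(frozen=True)
class HeadModel:
    """Three-shell concentric spherical conductor.

    Parameters
    ----------
    radii : tuple of float
        Outer radii (m) of the brain, skull and scalp shells, strictly
        increasing.
    conductivities : tuple of float
        Conductivities (S/m) of the brain, skull and scalp layers, ordered
        inner to outer.
    n_terms : int
        Truncation order of the spherical-harmonic series.
    """

    radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]
    n_terms: int = DEFAULT_N_TERMS

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.shape != (3,) or np.any(r <= 0) or not np.all(np.diff(r) > 0):
            raise ValidationError(
                f"radii must be three strictly increasing positive lengths, got {self.radii}"
            )
        s = np.asarray(self.conductivities, dtype=float)
        if s.shape != (3,) or np.any(s <= 0):
            raise ValidationError(
                f"conductivities must be three positive values, got {self.conductivities}"
            )
        if int(self.n_terms) < 1:
            raise ValidationError(f"n_terms must be >= 1, got {self.n_terms}")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[2]


def build_head_model(
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = PAPER_CONDUCTIVITIES,
    n_terms: int = DEFAULT_N_TERMS,
    assignment: str = "printed",
) -> HeadModel:
    """Build a validated three-sphere head model.

    ``conductivities`` is the (brain, scalp, skull) triple; the default is the
    study's published values interpreted as S/m.  ``assignment="printed"``
    honors that ordering (brain 0.33, scalp 0.022, skull 0.013);
    ``assignment="conventional"`` instead reads the triple as
    (brain, skull, scalp), the ordering conventional head models use where the
    skull is the second, poorly conducting layer.
    """
    b, x, y = (float(v) for v in conductivities)
    if assignment == "printed":
        sigma = (b, y, x)  # inner->outer: brain, skull, scalp
    elif assignment == "conventional":
        sigma = (b, x, y)
    else:
        raise ValidationError(f"unknown conductivity assignment {assignment!r}")
    return HeadModel(radii=tuple(float(v) for v in radii), conductivities=sigma,
                     n_terms=int(n_terms))


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode montage on the unit scalp sphere.

    positions are unit vectors (x toward the nasion, y toward the left ear,
    z up); ``reference`` is the unit vector of the reference point.
    """

    names: tuple[str, ...]
    positions: np.ndarray          # (n_channels, 3) unit vectors
    reference: np.ndarray          # (3,) unit vector

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValidationError(f"duplicate channel labels: {dup}")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("channel positions must be unit vectors")
        if abs(np.linalg.norm(self.reference) - 1.0) > 1e-9:
            raise ValidationError("reference position must be a unit vector")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _angles_to_unit(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def _parse_montage_rows(rows) -> Montage:
    names, az, el = [], [], []
    ref = None
    for row in rows:
        name, a, e = str(row[0]), float(row[1]), float(row[2])
        if name.upper() == "REF":
            ref = _angles_to_unit(np.array(a), np.array(e))
            continue
        names.append(name)
        az.append(a)
        el.append(e)
    if ref is None:
        ref = _angles_to_unit(np.array(0.0), np.array(-30.0))
    pos = _angles_to_unit(np.array(az), np.array(el))
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        warnings.warn("non-unit channel positions normalized", stacklevel=3)
        pos = pos / norms
    return Montage(names=tuple(names), positions=pos, reference=np.asarray(ref, float))


def build_montage(preset="paper60") -> Montage:
    """Build a montage from the ``"paper60"`` preset, a file path, or a table.

    The preset is the 60-channel extended 10/20 layout (nose reference).  A
    table is an iterable of ``(name, azimuth_deg, elevation_deg)`` rows; a row
    named ``REF`` gives the reference position.  A file uses the same
    whitespace-delimited columns with ``#`` comments.
    """
    if isinstance(preset, str) and preset == "paper60":
        text = (resources.files("erpsource.data") / "paper60_montage.txt").read_text()
        rows = [ln.split() for ln in text.splitlines()
                if ln.strip() and not ln.startswith("#")]
        return _parse_montage_rows(rows)
    if isinstance(preset, str):
        with open(preset) as fh:
            rows = [ln.split() for ln in fh
                    if ln.strip() and not ln.startswith("#")]
        return _parse_montage_rows(rows)
    return _parse_montage_rows(list(preset))


# ---------------------------------------------------------------------------
# Source space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpace:
    """Generators on a cortical shell, partitioned into labeled compartments."""

    positions: np.ndarray              # (G, 3) meters
    compartment_labels: np.ndarray     # (G,) int
    atlas: dict                        # label -> compartment name
    neighbor_graph: csr_matrix         # symmetric (G, G) adjacency

    @property
    def n_generators(self) -> int:
        return self.positions.shape[0]

    @property
    def n_compartments(self) -> int:
        return len(self.atlas)

    def generators_in(self, labels) -> np.ndarray:
        """Indices of generators whose compartment label is in ``labels``."""
        labels = np.atleast_1d(labels)
        return np.flatnonzero(np.isin(self.compartment_labels, labels))

    def compartment_centroid(self, label: int) -> np.ndarray:
        """Centroid of a compartment's generators, projected back to the shell."""
        pts = self.positions[self.compartment_labels == label]
        c = pts.mean(axis=0)
        radius = np.linalg.norm(pts, axis=1).mean()
        return c / np.linalg.norm(c) * radius


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_source_space(
    n_generators: int = 500,
    n_compartments: int = 12,
    seed: int = 0,
    brain_radius: float = DEFAULT_RADII[0],
    shell_fraction: float = 0.9,
    k_neighbors: int = 6,
) -> SourceSpace:
    """Quasi-uniform generator shell partitioned into contiguous compartments.

    Generators are placed on a sphere at ``shell_fraction`` of the brain
    radius; compartments are the spherical Voronoi cells of ``n_compartments``
    seed directions drawn deterministically from ``seed`` (redrawn until every
    cell is nonempty).  The neighbor graph links each generator to its
    ``k_neighbors`` nearest neighbors, symmetrized.
    """
    if n_compartments < 1 or n_generators < n_compartments:
        raise ValidationError(
            f"need n_generators >= n_compartments >= 1, got {n_generators}, {n_compartments}"
        )
    rng = np.random.default_rng(seed)
    unit = _fibonacci_sphere(n_generators)
    positions = unit * (shell_fraction * brain_radius)

    for _ in range(200):
        seeds = rng.normal(size=(n_compartments, 3))
        seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
        labels = np.argmax(unit @ seeds.T, axis=1)
        if len(np.unique(labels)) == n_compartments:
            break
    else:  # pragma: no cover - virtually impossible for sane sizes
        raise RuntimeError("could not draw a seed set with all compartments nonempty")

    atlas = {int(k): f"region_{k:02d}" for k in range(n_compartments)}

    tree = cKDTree(positions)
    k = min(k_neighbors + 1, n_generators)
    _, idx = tree.query(positions, k=k)
    rows = np.repeat(np.arange(n_generators), k - 1)
    cols = idx[:, 1:].ravel()
    data = np.ones_like(rows, dtype=float)
    adj = csr_matrix((data, (rows, cols)), shape=(n_generators, n_generators))
    adj = ((adj + adj.T) > 0).astype(float)

    return SourceSpace(positions=positions, compartment_labels=labels.astype(int),
                       atlas=atlas, neighbor_graph=adj)


# ---------------------------------------------------------------------------
# Lead field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadField:
    """Channels x (3*G) gain matrix in µV per nA·m, nose-referenced.

    Columns come in triplets (x, y, z moment components) per generator.
    """

    matrix: np.ndarray
    channel_names: tuple[str, ...]
    n_generators: int
    reference_applied: bool = True
    units: str = "uV / (nA m)"

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.channel_names), 3 * self.n_generators):
            raise ValidationError("lead field shape inconsistent with channels/generators")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("lead field contains non-finite entries")

    def columns(self, generator_indices) -> np.ndarray:
        """Sub-matrix with the 3 moment columns of each requested generator."""
        gi = np.atleast_1d(generator_indices)
        cols = (3 * gi[:, None] + np.arange(3)[None, :]).ravel()
        return self.matrix[:, cols]


def _radial_transfer(head: HeadModel) -> np.ndarray:
    """Per-order transfer factors s_n of the three-shell conductor.

    s_n is defined so that the surface potential of harmonic order n equals
    ``s_n * B1_n * R^-(n+1)`` where B1_n is the source coefficient of the
    infinite-medium (brain conductivity) expansion and R the scalp radius.
    For equal conductivities s_n reduces to the homogeneous-sphere factor
    (2n+1)/n.
    """
    r1, r2, r3 = (r / head.radii[2] for r in head.radii)  # normalized, r3 = 1
    s1, s2, s3 = head.conductivities
    out = np.empty(head.n_terms)
    for i, n in enumerate(range(1, head.n_terms + 1)):
        # unknowns: A1, A2, B2, A3, B3  (B1 = 1)
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at r1
        M[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # radial current continuity at r1
        M[1] = [s1 * n * r1 ** (n - 1),
                -s2 * n * r1 ** (n - 1),
                s2 * (n + 1) * r1 ** -(n + 2), 0, 0]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        M[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # radial current continuity at r2
        M[3] = [0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
                -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)]
        # zero radial current at the scalp surface (r3 = 1)
        M[4] = [0, 0, 0, s3 * n, -s3 * (n + 1)]
        sol = np.linalg.solve(M, rhs)
        out[i] = sol[3] + sol[4]  # A3 * 1 + B3 * 1
    return out


def _legendre_tables(x: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P'_n(x) for n = 1..n_max via stable upward recurrences."""
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], dP[0] = 1.0, 0.0
    if n_max >= 1:
        P[1], dP[1] = x, 1.0
    for n in range(2, n_max + 1):
        P[n] = ((2 * n - 1) * x * P[n - 1] - (n - 1) * P[n - 2]) / n
        dP[n] = n * P[n - 1] + x * dP[n - 1]
    return P[1:], dP[1:]


def dipole_potentials(
    head: HeadModel,
    electrode_units: np.ndarray,
    source_positions: np.ndarray,
    transfer: np.ndarray | None = None,
) -> np.ndarray:
    """Unreferenced scalp potentials of unit dipoles, series solution.

    Parameters
    ----------
    electrode_units : (C, 3) unit vectors on the scalp sphere.
    source_positions : (G, 3) dipole positions in meters, strictly inside the
        brain shell.
    transfer : precomputed ``_radial_transfer(head)`` (optional).

    Returns
    -------
    (C, G, 3) potentials in volts per A·m of dipole moment along x, y, z.
    """
    elec = np.asarray(electrode_units, float)
    srcs = np.atleast_2d(np.asarray(source_positions, float))
    R = head.scalp_radius
    sigma1 = head.conductivities[0]
    b = np.linalg.norm(srcs, axis=1)
    if np.any(b >= head.brain_radius):
        raise ValidationError("generator positions must lie strictly inside the brain shell")
    worst = (b.max() / head.scalp_radius) ** head.n_terms if b.max() > 0 else 0.0
    if worst > 1e-6:
        warnings.warn(
            f"series tail ratio {worst:.2e} exceeds 1e-6; increase n_terms",
            stacklevel=2,
        )
    if transfer is None:
        transfer = _radial_transfer(head)
    ns = np.arange(1, head.n_terms + 1)

    out = np.empty((elec.shape[0], srcs.shape[0], 3))
    for g, (pos, bg) in enumerate(zip(srcs, b)):
        if bg == 0.0:
            r0 = np.array([0.0, 0.0, 1.0])
        else:
            r0 = pos / bg
        x = np.clip(elec @ r0, -1.0, 1.0)          # (C,)
        Pn, dPn = _legendre_tables(x, head.n_terms)  # (N, C)
        coef = transfer * bg ** (ns - 1) / R ** (ns + 1)  # (N,)
        radial_series = (coef * ns) @ Pn           # (C,)
        tangential_series = coef @ dPn             # (C,)
        tang = elec - x[:, None] * r0[None, :]     # (C, 3), magnitude sin(gamma)
        block = (radial_series[:, None] * r0[None, :]
                 + tangential_series[:, None] * tang)
        out[:, g, :] = block / (4.0 * np.pi * sigma1)
    return out


def compute_lead_field(head: HeadModel, montage: Montage, space: SourceSpace) -> LeadField:
    """Nose-referenced electric lead field of the source space.

    The series solution is evaluated at every channel and at the reference
    position; the reference potential is subtracted from every channel row, so
    predicted potentials vanish at the reference point.  Entries are stored in
    µV per nA·m.
    """
    elec = np.vstack([montage.positions, montage.reference[None, :]])
    pots = dipole_potentials(head, elec, space.positions)  # (C+1, G, 3), V / (A m)
    pots = pots - pots[-1:, :, :]
    pots = pots[:-1]
    matrix = pots.reshape(montage.n_channels, 3 * space.n_generators) * 1e-3
    return LeadField(matrix=matrix, channel_names=montage.names,
                     n_generators=space.n_generators, reference_applied=True)


def homogeneous_sphere_potential(
    radius: float,
    sigma: float,
    electrode_units: np.ndarray,
    source_position: np.ndarray,
    moment: np.ndarray,
) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Independent analytic formula (resummed harmonic series): with t = b/R and
    x = cos of the source-electrode angle,

        V = 2*V_inf + (1 / (4 pi sigma b R)) * [ m_r (F - 1)
              + m_t ( (t - x) F / sin(g) + x / sin(g) ) ],   F = R / d,

    where V_inf is the infinite-medium dipole potential at the electrode,
    m_r / m_t the radial / tangential moment components and d the
    source-electrode distance.  Used as the oracle for the layered series in
    the equal-conductivity limit.
    """
    elec = np.asarray(electrode_units, float) * radius
    pos = np.asarray(source_position, float)
    m = np.asarray(moment, float)
    b = np.linalg.norm(pos)
    if b == 0:
        raise ValidationError("closed form requires an off-center dipole")
    r0 = pos / b
    d_vec = elec - pos[None, :]
    d = np.linalg.norm(d_vec, axis=1)
    v_inf = (d_vec @ m) / d**3 / (4 * np.pi * sigma)

    x = np.clip((elec / radius) @ r0, -1.0, 1.0)
    t = b / radius
    F = radius / d
    m_r = m @ r0
    tang_dir = elec / radius - x[:, None] * r0[None, :]
    sin_g = np.linalg.norm(tang_dir, axis=1)
    m_t = np.zeros_like(x)
    ok = sin_g > 1e-12
    m_t[ok] = (tang_dir[ok] / sin_g[ok, None]) @ m

    corr = np.zeros_like(x)
    corr += m_r * (F - 1.0)
    corr[ok] += m_t[ok] * ((t - x[ok]) * F[ok] + x[ok]) / sin_g[ok]
    return 2.0 * v_inf + corr / (4 * np.pi * sigma * b * radius)
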
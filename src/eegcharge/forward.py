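"""Spherical-head EEG forward model.

Sensor montage on the scalp sphere, a parcellated source space (cortical
Brodmann areas plus the deep parcels amygdala and hippocampus), and an
analytic lead field for a dipole inside concentric conducting shells
(brain / skull / scalp).

Conventions: right-handed coordinates, origin at the sphere center, x to the
right, y anterior, z up; all lengths in meters.  Lead-field gain is in μV of
scalp potential per unit dipole moment, where one source unit corresponds to
a 10 nA·m equivalent current dipole (a typical synchronized cortical patch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "SourceSpace",
    "LeadField",
    "ShellModel",
    "build_spherical_montage",
    "build_source_space",
    "compute_lead_field",
    "default_parcel_spec",
    "default_shells",
    "PARCEL_VOCABULARY",
]

#: Controlled parcel vocabulary: Brodmann areas 4..47 plus two deep structures.
PARCEL_VOCABULARY = frozenset(
    {f"BA{i:02d}" for i in range(4, 48)} | {"AMYGDALA", "HIPPOCAMPUS"}
)

#: Parcels excluded from most-active selection (primary somatosensory cortex,
#: hyperactive from response-pad fingertip contact).
SOMATOSENSORY_EXCLUSIONS = frozenset({"BA01", "BA02", "BA03"})

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Internal dipole-moment unit in A·m (10 nA·m) behind the "μA"-convention
#: amplitudes used throughout the package.
MOMENT_UNIT_AM = 1e-8


class MontageError(ValueError):
    """Invalid sensor montage."""


class GeometryError(ValueError):
    """Source/shell geometry violation."""


@dataclass(frozen=True)
class Montage:
    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), meters
    scalp_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.channel_ids) < 8:
            raise MontageError("montage needs at least 8 channels")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise MontageError("channel ids must be unique")
        if pos.shape != (len(self.channel_ids), 3):
            raise MontageError("positions must be (n_channels, 3)")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, self.scalp_radius, atol=1e-6):
            raise MontageError("all sensors must lie on the scalp sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def frontal_channels(self, min_y_frac: float = 0.3) -> list[str]:
        """Channels in the anterior scalp region (y above a radius fraction)."""
        mask = self.positions[:, 1] > min_y_frac * self.scalp_radius
        return [cid for cid, m in zip(self.channel_ids, mask) if m]


@dataclass(frozen=True)
class SourceSpace:
    locations: np.ndarray  # (M, 3), meters, inside the inner shell
    parcel_labels: tuple[str, ...]  # one label per source
    depth_class: dict[str, str]  # parcel -> {"cortical", "deep"}
    orientation_mode: str = "free"

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        object.__setattr__(self, "locations", loc)
        if loc.shape != (len(self.parcel_labels), 3):
            raise GeometryError("locations must be (M, 3) matching labels")
        unknown = set(self.parcel_labels) - PARCEL_VOCABULARY
        if unknown:
            raise GeometryError(f"labels outside vocabulary: {sorted(unknown)}")
        if self.orientation_mode not in ("free", "fixed"):
            raise GeometryError("orientation_mode must be 'free' or 'fixed'")
        radii = np.linalg.norm(loc, axis=1)
        deep_r = [r for r, p in zip(radii, self.parcel_labels)
                  if self.depth_class.get(p) == "deep"]
        cort_r = [r for r, p in zip(radii, self.parcel_labels)
                  if self.depth_class.get(p) == "cortical"]
        if deep_r and cort_r and max(deep_r) >= min(cort_r):
            raise GeometryError("deep sources must sit at smaller radii than "
                                "cortical sources")

    @property
    def n_sources(self) -> int:
        return len(self.parcel_labels)

    @property
    def parcels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.parcel_labels:
            seen.setdefault(p)
        return tuple(seen)

    def sources_of(self, parcel: str) -> np.ndarray:
        """Indices of the sources belonging to ``parcel``."""
        idx = np.flatnonzero(np.asarray(self.parcel_labels) == parcel)
        if idx.size == 0:
            raise GeometryError(f"parcel {parcel!r} has no sources")
        return idx


@dataclass(frozen=True)
class ShellModel:
    """Concentric conducting shells, ordered inner to outer."""

    radii: tuple[float, ...]  # meters
    conductivities: tuple[float, ...]  # S/m

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise GeometryError("radii and conductivities must match")
        if any(np.diff(self.radii) <= 0):
            raise GeometryError("shell radii must increase inner to outer")
        if any(s <= 0 for s in self.conductivities):
            raise GeometryError("conductivities must be positive")

    @property
    def inner_radius(self) -> float:
        return self.radii[0]

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]


@dataclass(frozen=True)
class LeadField:
    gain: np.ndarray  # (n_sensors, 3*M) free / (n_sensors, M) fixed
    average_referenced: bool
    orientation_mode: str
    n_sources: int

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        if not np.all(np.isfinite(g)):
            raise GeometryError("lead field contains non-finite entries")
        if self.average_referenced:
            col = g.sum(axis=0)
            scale = max(np.abs(g).max(), 1.0)
            if np.abs(col).max() > 1e-9 * scale * g.shape[0]:
                raise GeometryError("average-referenced columns must sum to 0")


def default_shells() -> ShellModel:
    """Three-shell head: brain 0.08 m / skull 0.085 m / scalp 0.09 m.

    Conductivities 0.33 / 0.0042 / 0.33 S/m (standard 1:1/80:1 ratio).
    """
    return ShellModel(radii=(0.08, 0.085, 0.09),
                      conductivities=(0.33, 0.0042, 0.33))


def build_spherical_montage(n_channels: int, scalp_radius: float = 0.09,
                            prefix: str = "E") -> Montage:
    """Quasi-uniform sensors on the upper hemisphere of the scalp sphere.

    Uses a golden-angle (Fibonacci) spiral restricted to z > 0; deterministic
    for a fixed channel count.
    """
    if n_channels < 8:
        raise MontageError("n_channels must be >= 8")
    k = np.arange(n_channels)
    z = (k + 0.5) / n_channels  # (0, 1): upper hemisphere
    phi = k * _GOLDEN_ANGLE
    rho = np.sqrt(1.0 - z**2)
    pos = scalp_radius * np.column_stack(
        [rho * np.cos(phi), rho * np.sin(phi), z])
    ids = tuple(f"{prefix}{i + 1:03d}" for i in k)
    return Montage(channel_ids=ids, positions=pos, scalp_radius=scalp_radius)


def default_parcel_spec(n_sources: int = 1) -> dict:
    """Default 12-parcel source space.

    Directions are schematic (motor strip superior, visual cortex posterior,
    prefrontal anterior, limbic structures deep and inferior), not atlas
    coordinates.  Radii put the two deep parcels well below the cortical
    shell.
    """
    def at(direction, radius):
        d = np.asarray(direction, dtype=float)
        return d / np.linalg.norm(d) * radius

    spec = {
        "AMYGDALA": (at((0.55, 0.45, -0.35), 0.030), n_sources, "deep"),
        "HIPPOCAMPUS": (at((-0.65, -0.25, -0.25), 0.032), n_sources, "deep"),
        "BA04": (at((0.35, -0.10, 0.93), 0.071), n_sources, "cortical"),
        "BA05": (at((0.30, -0.55, 0.78), 0.071), n_sources, "cortical"),
        "BA09": (at((0.35, 0.75, 0.55), 0.070), n_sources, "cortical"),
        "BA17": (at((0.10, -0.95, 0.20), 0.070), n_sources, "cortical"),
        "BA27": (at((0.40, -0.70, -0.20), 0.066), n_sources, "cortical"),
        "BA29": (at((0.10, -0.90, -0.05), 0.065), n_sources, "cortical"),
        "BA34": (at((0.60, 0.50, -0.20), 0.066), n_sources, "cortical"),
        "BA36": (at((0.80, -0.30, -0.20), 0.067), n_sources, "cortical"),
        "BA45": (at((0.80, 0.50, 0.10), 0.068), n_sources, "cortical"),
        "BA46": (at((0.60, 0.65, 0.30), 0.069), n_sources, "cortical"),
    }
    return spec


def build_source_space(parcel_spec: dict, orientation_mode: str = "free",
                       inner_radius: float = 0.08,
                       jitter_m: float = 0.003,
                       seed: int = 0) -> SourceSpace:
    """Build a labeled source space from ``parcel -> (centroid, n, depth)``.

    Single-source parcels sit exactly at their centroid; multi-source parcels
    are jittered around it with a seeded generator (deterministic).
    """
    rng = np.random.default_rng(seed)
    locations: list[np.ndarray] = []
    labels: list[str] = []
    depth: dict[str, str] = {}
    for parcel in sorted(parcel_spec):
        centroid, n, depth_class = parcel_spec[parcel]
        centroid = np.asarray(centroid, dtype=float)
        if parcel not in PARCEL_VOCABULARY:
            raise GeometryError(f"unknown parcel {parcel!r}")
        if n < 1:
            raise GeometryError("each parcel needs at least one source")
        if np.linalg.norm(centroid) >= inner_radius:
            raise GeometryError(
                f"centroid of {parcel} outside the inner shell")
        depth[parcel] = depth_class
        for j in range(n):
            if j == 0:
                loc = centroid
            else:
                loc = centroid + rng.normal(0.0, jitter_m, 3)
                r = np.linalg.norm(loc)
                if r >= 0.98 * inner_radius:
                    loc = loc / r * 0.98 * inner_radius
            locations.append(loc)
            labels.append(parcel)
    return SourceSpace(locations=np.asarray(locations),
                       parcel_labels=tuple(labels),
                       depth_class=depth,
                       orientation_mode=orientation_mode)


def _shell_transfer(n_terms: int, shells: ShellModel) -> np.ndarray:
    """Per-degree transfer coefficients s_n of the layered sphere.

    For each harmonic degree n the radial potential in layer k is
    ``A_k ρ^n + B_k ρ^-(n+1)`` (ρ = r / outer radius), with the source's
    particular term ``ρ^-(n+1)`` of unit coefficient added in the innermost
    layer.  Continuity of potential and radial current at the interfaces plus
    the insulating outer boundary determine the coefficients; s_n is the
    resulting surface potential for a unit particular term.  A single layer
    gives the classic s_n = (2n+1)/n.
    """
    L = len(shells.radii)
    R = shells.outer_radius
    rho = np.asarray(shells.radii) / R  # interface radii, rho[-1] = 1
    sig = np.asarray(shells.conductivities)
    s = np.empty(n_terms + 1)
    s[0] = 0.0
    for n in range(1, n_terms + 1):
        # unknowns: A_1, (A_2, B_2), ..., (A_L, B_L)  -> 2L-1
        m = 2 * L - 1
        A = np.zeros((m, m))
        b = np.zeros(m)

        def col_A(k: int) -> int:  # layer index k = 0..L-1
            return 0 if k == 0 else 2 * k - 1

        def col_B(k: int) -> int:
            return 2 * k

        row = 0
        for k in range(L - 1):  # interface between layer k and k+1 at rho[k]
            r = rho[k]
            # potential continuity
            A[row, col_A(k)] = r**n
            if k > 0:
                A[row, col_B(k)] = r ** -(n + 1)
            A[row, col_A(k + 1)] = -(r**n)
            A[row, col_B(k + 1)] = -(r ** -(n + 1))
            if k == 0:
                b[row] = -(r ** -(n + 1))  # particular term in layer 0
            row += 1
            # radial current continuity
            A[row, col_A(k)] = sig[k] * n * r ** (n - 1)
            if k > 0:
                A[row, col_B(k)] = -sig[k] * (n + 1) * r ** -(n + 2)
            A[row, col_A(k + 1)] = -sig[k + 1] * n * r ** (n - 1)
            A[row, col_B(k + 1)] = sig[k + 1] * (n + 1) * r ** -(n + 2)
            if k == 0:
                b[row] = sig[0] * (n + 1) * r ** -(n + 2)
            row += 1
        # insulating scalp: dV/dr = 0 at rho = 1
        if L == 1:
            A[row, col_A(0)] = n
            b[row] = n + 1
        else:
            A[row, col_A(L - 1)] = n
            A[row, col_B(L - 1)] = -(n + 1)
        x = np.linalg.solve(A, b)
        if L == 1:
            s[n] = 1.0 + x[col_A(0)]
        else:
            s[n] = x[col_A(L - 1)] + x[col_B(L - 1)]
    return s


def compute_lead_field(montage: Montage, source_space: SourceSpace,
                       shells: ShellModel | None = None,
                       n_terms: int = 150,
                       average_reference: bool = True) -> LeadField:
    """Analytic lead field of dipoles inside concentric shells.

    Scalp potential of a dipole q at position b, evaluated at a surface
    sensor e, as a Legendre series over degrees n with layered-sphere
    transfer coefficients s_n::

        V = 1/(4 π σ_1 R²) Σ_n s_n x^(n-1)
            [ n P_n(u) (q·b̂) + P_n'(u) (q·ê − u (q·b̂)) ]

    with x = |b|/R and u = b̂·ê.  Gain is returned in μV per source unit
    (10 nA·m); for ``fixed`` orientation the dipole is radial.
    """
    if shells is None:
        shells = default_shells()
    R = shells.outer_radius
    if abs(montage.scalp_radius - R) > 1e-9:
        raise GeometryError("montage radius must equal the outer shell radius")
    loc = source_space.locations
    src_r = np.linalg.norm(loc, axis=1)
    if np.any(src_r >= shells.inner_radius):
        raise GeometryError("all sources must lie inside the inner shell")
    if np.any(src_r < 1e-12):
        raise GeometryError("source at the sphere center is degenerate")

    e_hat = montage.positions / R  # (N, 3)
    b_hat = loc / src_r[:, None]  # (M, 3)
    x = src_r / R  # (M,)
    u = e_hat @ b_hat.T  # (N, M)
    s = _shell_transfer(n_terms, shells)

    # Legendre recurrences, accumulated sums S1 = Σ s_n x^{n-1} n P_n(u),
    # S2 = Σ s_n x^{n-1} P_n'(u).
    P_prev = np.ones_like(u)  # P_0
    P_cur = u.copy()  # P_1
    dP_prev = np.zeros_like(u)  # P_0'
    dP_cur = np.ones_like(u)  # P_1'
    xpow = np.ones_like(x)  # x^{n-1}
    S1 = s[1] * xpow * 1.0 * P_cur
    S2 = s[1] * xpow * dP_cur
    for n in range(1, n_terms):
        P_next = ((2 * n + 1) * u * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        xpow = xpow * x
        w = s[n + 1] * xpow
        S1 += w * (n + 1) * P_next
        S2 += w * dP_next
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next

    pref = 1.0 / (4.0 * np.pi * shells.conductivities[0] * R**2)
    scale = pref * 1e6 * MOMENT_UNIT_AM  # μV per source unit
    N, M = u.shape
    gain = np.empty((N, 3 * M))
    for a in range(3):
        # V for a unit dipole along axis a: S1 (ê_a·b̂) + S2 (ê_a·ê − u ê_a·b̂)
        ba = b_hat[:, a][None, :]
        ea = e_hat[:, a][:, None]
        gain[:, a::3] = scale * (S1 * ba + S2 * (ea - u * ba))

    if source_space.orientation_mode == "fixed":
        fixed = np.empty((N, M))
        for j in range(M):
            fixed[:, j] = gain[:, 3 * j:3 * j + 3] @ b_hat[j]
        gain = fixed

    if average_reference:
        gain = gain - gain.mean(axis=0, keepdims=True)
    return LeadField(gain=gain, average_referenced=average_reference,
                     orientation_mode=source_space.orientation_mode,
                     n_sources=M)
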
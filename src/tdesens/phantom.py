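"""Synthetic voxel body phantoms and rectal-probe geometry.

The individual whose CT scan underlies published postmortem-cooling FE
models is never public, so this module builds a *synthetic* stand-in: a
labelled voxel volume on a regular grid with distinct tissue compartments
(muscle, subcutaneous fat, bone/spine, abdominal viscera, lungs), a rectal
measurement locus C deep in the pelvic trunk with the spine dorsal to it,
an optional wet-soil slab under the back, and a left-right asymmetric
variant with perturbed organ positions.

Axis convention: X lateral (mid-sagittal mirror plane at the grid centre),
Y dorsal (-) to ventral (+), Z caudal (-) to cranial (+).  All lengths in
metres, masses in kg.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TissueProperties",
    "Phantom",
    "PhantomSpec",
    "ProbeSet",
    "SizingError",
    "AIR",
    "MUSCLE",
    "FAT",
    "BONE",
    "VISCERA",
    "LUNG",
    "SUBSTRATE",
    "default_tissues",
    "build_phantom",
    "scale_phantom",
    "add_substrate",
    "make_octahedron_probes",
    "label_at",
]

# tissue label codes; 0 is reserved for exterior air
AIR = 0
MUSCLE = 1
FAT = 2
BONE = 3
VISCERA = 4
LUNG = 5
SUBSTRATE = 9


class SizingError(ValueError):
    """Grid or geometry cannot accommodate the requested probe layout."""


@dataclass(frozen=True)
class TissueProperties:
    """Thermal material properties of one tissue compartment.

    kappa  : thermal conductivity, W/(m K)
    rho    : mass density, kg/m^3
    c      : specific heat capacity, J/(kg K)
    w      : blood perfusion rate, 1/s (only the steady bioheat
             initial-field solve uses it; it is zero postmortem)
    emissivity : surface emissivity in [0, 1], used for the linearised
             radiation part of the boundary condition
    """

    name: str
    kappa: float
    rho: float
    c: float
    w: float = 0.0
    emissivity: float = 0.95

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.rho > 0 and self.c > 0):
            raise ValueError(f"{self.name}: kappa, rho, c must be positive")
        if self.w < 0:
            raise ValueError(f"{self.name}: perfusion w must be >= 0")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError(f"{self.name}: emissivity must lie in [0, 1]")


def default_tissues() -> dict[int, TissueProperties]:
    """Literature-typical tissue property table (see docs/methods.md).

    Values are documented defaults, overridable per phantom; the CSV they
    come from ships with the package (``data/tissue_defaults.csv``).
    """
    path = importlib.resources.files("tdesens.data") / "tissue_defaults.csv"
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p)
    return {
        int(row["label"]): TissueProperties(
            name=str(row["name"]),
            kappa=float(row["kappa"]),
            rho=float(row["rho"]),
            c=float(row["c"]),
            w=float(row["w"]),
            emissivity=float(row["emissivity"]),
        )
        for _, row in table.iterrows()
    }


@dataclass
class Phantom:
    """Labelled voxel body on a regular (per-axis) grid.

    labels  : int array (nx, ny, nz); 0 = exterior air
    spacing : voxel edge lengths (dx, dy, dz), m
    origin  : position of the grid corner (voxel centres sit at
              origin + (i + 1/2) * spacing), m
    tissues : label -> TissueProperties
    rectal_probe : the central measurement point C, m
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    tissues: dict[int, TissueProperties]
    rectal_probe: np.ndarray
    length: float
    declared_mass: float

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def mass(self) -> float:
        """Voxel-integrated body mass (excludes any substrate slab)."""
        m = 0.0
        for lab, props in self.tissues.items():
            if lab in (AIR, SUBSTRATE):
                continue
            m += props.rho * np.count_nonzero(self.labels == lab)
        return m * self.voxel_volume

    @property
    def body_mask(self) -> np.ndarray:
        return (self.labels != AIR) & (self.labels != SUBSTRATE)

    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.tissues) - {AIR}
        if missing:
            raise ValueError(f"labels without tissue entry: {sorted(missing)}")
        if abs(self.mass - self.declared_mass) > 0.02 * self.declared_mass:
            raise ValueError(
                f"voxel mass {self.mass:.2f} kg deviates >2% from declared "
                f"{self.declared_mass:.2f} kg"
            )


@dataclass(frozen=True)
class ProbeSet:
    """Central point C plus six octahedron vertices SP_1..SP_6.

    SP_1/2 displace C along +/-X (lateral), SP_3 along -Y (dorsal, toward
    the spine), SP_4 along +Y (ventral, centre of abdomen), SP_5 along +Z
    (cranial), SP_6 along -Z (caudal).
    """

    C: np.ndarray
    R: float
    SP: np.ndarray  # (6, 3)

    PROBE_IDS = ("C", "SP_1", "SP_2", "SP_3", "SP_4", "SP_5", "SP_6")
    AXIS_OF = {"SP_1": "X", "SP_2": "X", "SP_3": "Y", "SP_4": "Y",
               "SP_5": "Z", "SP_6": "Z"}

    def points(self) -> dict[str, np.ndarray]:
        d = {"C": self.C}
        for k in range(6):
            d[f"SP_{k + 1}"] = self.SP[k]
        return d


def make_octahedron_probes(C, R: float) -> ProbeSet:
    """Octahedron of misplaced-sensor positions around the locus C."""
    if R <= 0:
        raise ValueError("octahedron radius R must be positive")
    C = np.asarray(C, dtype=float)
    ex, ey, ez = np.eye(3)
    SP = np.stack([
        C + R * ex,   # SP_1 lateral +X
        C - R * ex,   # SP_2 lateral -X
        C - R * ey,   # SP_3 dorsal, nearby bone
        C + R * ey,   # SP_4 ventral, centre of abdomen
        C + R * ez,   # SP_5 cranial
        C - R * ez,   # SP_6 caudal
    ])
    return ProbeSet(C=C, R=float(R), SP=SP)


def label_at(p: Phantom, point) -> int:
    """Tissue label of the voxel containing a physical point."""
    idx = np.floor((np.asarray(point, float) - p.origin) / p.spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= p.labels.shape):
        return AIR
    return int(p.labels[tuple(idx)])


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe parameters for the synthetic body.

    The default recipe is an adult male analog that is scaled after
    construction to exactly ``length`` / ``mass`` (head-to-foot 1.74 m,
    62 kg, the reference body of the study conditions).
    """

    spacing: float = 0.01           # isotropic voxel edge before scaling, m
    length: float = 1.74            # target head-to-foot extent, m
    mass: float = 62.0              # target body mass, kg
    symmetric: bool = True          # False = asymmetric organ layout
    r_max: float = 0.02             # largest probe octahedron radius, m
    seed: int = 0                   # jitter seed for the asymmetric variant
    bottom_margin: float = 0.06     # air gap under the back, reserved for slab
    tissues: dict[int, TissueProperties] | None = None


def _ellipsoid(X, Y, Z, c, s):
    return ((X - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2 \
        + ((Z - c[2]) / s[2]) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the synthetic body and scale it to the target length/mass.

    Raises :class:`SizingError` if the octahedron of radius ``spec.r_max``
    around the rectal locus does not fit inside body tissue.
    """
    spec = spec or PhantomSpec()
    if spec.length <= 0 or spec.mass <= 0:
        raise ValueError("length and mass targets must be positive")
    h = spec.spacing
    tissues = dict(spec.tissues or default_tissues())

    rng = np.random.default_rng(spec.seed)
    if spec.symmetric:
        jx = jy = jz = np.zeros(4)
    else:
        # small seeded organ jitter; X offsets break the mirror symmetry
        jx = rng.uniform(-0.005, 0.005, 4) + np.array([0.015, 0.008, 0.01, -0.01])
        jy = rng.uniform(-0.004, 0.004, 4)
        jz = rng.uniform(-0.004, 0.004, 4)

    # nominal recipe coordinates (pre-scaling), m
    z0 = 0.03                       # feet position above the grid floor
    ymargin = spec.bottom_margin    # dorsal skin plane
    Lx, Ly, Lz = 0.44, 0.32, spec.length + 2 * z0
    nx = int(round(Lx / h))
    nx += nx % 2                    # even count -> mirror plane on a face
    ny, nz = int(round(Ly / h)), int(round(Lz / h))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    xc = nx * h / 2.0               # mid-sagittal plane
    yc = ymargin + 0.10             # trunk centre height

    z_leg0, z_leg1 = z0, z0 + 0.80
    z_tr0, z_tr1 = z0 + 0.80, z0 + 1.44
    z_nk0, z_nk1 = z0 + 1.44, z0 + 1.51
    z_hd1 = z0 + spec.length

    # --- outer body surface (everything muscle first) ---
    # thighs taper linearly toward the ankles; they attach to the pelvic
    # underside, leaving only the crotch area of that face exposed
    z_pel0 = z_tr0 - 0.05
    rthigh, rankle = 0.072, 0.045
    rleg = rthigh + (rankle - rthigh) * (z_pel0 - Z) / (z_pel0 - z_leg0)
    legs = (
        (np.minimum((X - (xc - 0.075)) ** 2, (X - (xc + 0.075)) ** 2)
         + (Y - (ymargin + rthigh)) ** 2 <= rleg ** 2)
        & (Z >= z_leg0) & (Z < z_pel0)
    )
    # trunk incl. the pelvis: full elliptic cross section down to the
    # perineal face at z_pel0 (the pelvis is the body's most massive ring)
    trunk = (
        ((X - xc) / 0.155) ** 2 + ((Y - yc) / 0.10) ** 2 <= 1.0
    ) & (Z >= z_pel0) & (Z < z_tr1)
    neck = ((X - xc) ** 2 + (Y - yc) ** 2 <= 0.05 ** 2) \
        & (Z >= z_nk0) & (Z < z_nk1)
    head = _ellipsoid(X, Y, Z, (xc, yc, (z_nk1 + z_hd1) / 2.0),
                      (0.08, 0.095, (z_hd1 - z_nk1) / 2.0))
    labels[legs | trunk | neck | head] = MUSCLE

    # --- subcutaneous fat shell of the trunk (outer ~15%) ---
    fat_shell = trunk & (
        ((X - xc) / 0.155) ** 2 + ((Y - yc) / 0.10) ** 2 > 0.85 ** 2
    )
    labels[fat_shell] = FAT

    # --- spine: bone cylinder along the trunk, dorsal of centre ---
    spine = (
        ((X - (xc + jx[1])) ** 2 + (Y - (yc - 0.062 + jy[1])) ** 2
         <= 0.022 ** 2)
        & (Z >= z_pel0) & (Z < z_tr1)
    )
    labels[spine] = BONE

    # --- lungs: two ellipsoids in the upper trunk ---
    for sx, kx in ((-1, 2), (1, 3)):
        lung = _ellipsoid(
            X, Y, Z,
            (xc + sx * 0.06 + jx[kx] * (0 if spec.symmetric else 1),
             yc + 0.01 + jy[kx], z_tr1 - 0.14 + jz[kx]),
            (0.05, 0.06, 0.10),
        )
        labels[lung & ~spine] = LUNG

    # --- abdominal/pelvic viscera: large ellipsoid reaching the pelvis ---
    viscera = _ellipsoid(
        X, Y, Z,
        (xc + jx[0], yc + 0.01 + jy[0], z_tr0 + 0.22 + jz[0]),
        (0.11, 0.075, 0.21),
    )
    labels[viscera & ~spine] = VISCERA

    if spec.symmetric:
        # exact mirror symmetry about the mid-sagittal plane (floating-point
        # ties on curved compartment boundaries would otherwise break it)
        labels[nx // 2:] = labels[:nx // 2][::-1]

    # rectal locus C: pelvic interior, spine dorsal within 3 cm, well
    # above the perineal face (deep rectal insertion)
    C = np.array([xc, yc - 0.02, z_tr0 + 0.12])

    phantom = Phantom(
        labels=labels,
        spacing=np.array([h, h, h]),
        origin=np.zeros(3),
        tissues=tissues,
        rectal_probe=C,
        length=spec.length,
        declared_mass=float(
            sum(tissues[lab].rho * np.count_nonzero(labels == lab)
                for lab in np.unique(labels) if lab != AIR) * h ** 3
        ),
    )
    phantom = scale_phantom(phantom, spec.length, spec.mass)

    probes = make_octahedron_probes(phantom.rectal_probe, spec.r_max)
    bad = [pid for pid, pt in probes.points().items()
           if label_at(phantom, pt) in (AIR, SUBSTRATE)]
    if bad:
        raise SizingError(
            f"octahedron of radius {spec.r_max} m does not fit in tissue "
            f"around C (offending probes: {bad}); refine the grid or reduce r_max"
        )
    phantom.validate()
    return phantom


def scale_phantom(p: Phantom, L_target: float, M_target: float) -> Phantom:
    """Geometric scaling to a target length and mass.

    One-dimensional stretch k1 = L'/L along the body (Z) axis and
    two-dimensional dilation k2 = sqrt(M' L / (M L')) in the transverse
    (XY) plane; densities unchanged, so mass scales by k1 * k2**2 and
    lands exactly on M'.
    """
    if L_target <= 0 or M_target <= 0:
        raise ValueError("scaling targets must be positive")
    L, M = p.length, p.mass
    if L <= 0 or M <= 0:
        raise ValueError("phantom must have positive length and mass")
    k1 = L_target / L
    k2 = float(np.sqrt(M_target * L / (M * L_target)))
    factors = np.array([k2, k2, k1])
    return replace(
        p,
        spacing=p.spacing * factors,
        origin=p.origin * factors,
        rectal_probe=p.rectal_probe * factors,
        length=L_target,
        declared_mass=M_target,
    )


def add_substrate(
    p: Phantom,
    props: TissueProperties | None = None,
    thickness: float = 0.05,
) -> Phantom:
    """Add a wet-soil slab in conductive contact with the dorsal skin.

    The slab occupies ``thickness`` metres under the body footprint and
    conforms upward to the dorsal body surface column by column (soft soil
    bed), guaranteeing a face-contact interface everywhere along the back.
    """
    if thickness <= 0:
        raise ValueError("substrate thickness must be positive")
    props = props or TissueProperties("wet_soil", kappa=2.0, rho=1900.0,
                                      c=2200.0, w=0.0, emissivity=0.95)
    labels = p.labels.copy()
    body = (labels != AIR) & (labels != SUBSTRATE)
    nt = max(1, int(round(thickness / p.spacing[1])))

    cols = body.any(axis=1)                       # (nx, nz) columns with body
    if not cols.any():
        raise ValueError("phantom contains no body voxels")
    ymin_col = np.where(cols, body.argmax(axis=1), labels.shape[1])
    floor = int(ymin_col[cols].min())
    if floor < nt:
        raise SizingError(
            "bottom margin too small for the requested slab thickness"
        )
    ix, iz = np.nonzero(cols)
    for x, z in zip(ix, iz):
        top = int(ymin_col[x, z])
        labels[x, max(0, top - nt):top, z] = SUBSTRATE
    tissues = dict(p.tissues)
    tissues[SUBSTRATE] = props
    return replace(p, labels=labels, tissues=tissues)
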
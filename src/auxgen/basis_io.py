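"""Reading and writing of orbital/auxiliary basis set definitions and geometries.

Orbital basis sets (OBS) are contracted Cartesian Gaussian shells; auxiliary
basis sets (ABS) are ordered shared-exponent sets of primitive Hermite
Gaussians.  Two text dialects are supported for each: the common Gaussian-style
block format (``gaussian_text``) resp. a deMon-style set listing
(``demon_text``), and a JSON mirror of either.  Geometries are standard XYZ.

All lengths are stored in bohr internally; angstrom appears only at the XYZ
boundary.  Gaussian exponents are in bohr^-2 throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANGSTROM_TO_BOHR",
    "PrimitiveGaussian",
    "ContractedShell",
    "AtomicOrbitalBasis",
    "HermiteAuxSet",
    "AtomicAuxBasis",
    "Molecule",
    "BasisParseError",
    "parse_orbital_basis",
    "write_orbital_basis",
    "parse_aux_basis",
    "write_aux_basis",
    "parse_molecule",
    "write_molecule",
]

ANGSTROM_TO_BOHR = 1.8897261254578281

#: shell labels in order of angular momentum; index == l
SHELL_LABELS = "SPDFGHI"

_ELEMENTS_H_TO_KR = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr"
).split()


class BasisParseError(ValueError):
    """Raised when a basis or geometry text block cannot be parsed."""


@dataclass(frozen=True)
class PrimitiveGaussian:
    """A single primitive Gaussian: exponent (bohr^-2) and contraction coefficient."""

    exponent: float
    coefficient: float = 1.0

    def __post_init__(self) -> None:
        if not self.exponent > 0:
            raise ValueError(f"primitive exponent must be positive, got {self.exponent}")
        if not np.isfinite(self.coefficient):
            raise ValueError("contraction coefficient must be finite")


@dataclass(frozen=True)
class ContractedShell:
    """A contracted shell of fixed angular momentum l built from primitives.

    Primitives are kept in descending-exponent order.
    """

    l: int
    primitives: tuple[PrimitiveGaussian, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.l <= 6):
            raise ValueError(f"angular momentum l must be in 0..6, got {self.l}")
        if len(self.primitives) < 1:
            raise ValueError("a shell needs at least one primitive")
        exps = [p.exponent for p in self.primitives]
        if any(a < b for a, b in zip(exps, exps[1:])):
            object.__setattr__(
                self,
                "primitives",
                tuple(sorted(self.primitives, key=lambda p: -p.exponent)),
            )

    @property
    def exponents(self) -> np.ndarray:
        return np.array([p.exponent for p in self.primitives])

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([p.coefficient for p in self.primitives])

    @property
    def n_cartesian(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


@dataclass(frozen=True)
class AtomicOrbitalBasis:
    """Orbital basis set of one element: a list of contracted shells."""

    element: str
    shells: tuple[ContractedShell, ...]

    def __post_init__(self) -> None:
        if len(self.shells) < 1:
            raise ValueError("an atomic basis needs at least one shell")
        if self.element not in _ELEMENTS_H_TO_KR:
            warnings.warn(
                f"element symbol {self.element!r} outside H-Kr; proceeding anyway",
                stacklevel=2,
            )

    @property
    def l_max(self) -> int:
        return max(s.l for s in self.shells)

    @property
    def n_cartesian(self) -> int:
        return sum(s.n_cartesian for s in self.shells)


@dataclass(frozen=True)
class HermiteAuxSet:
    """Shared-exponent set of primitive Hermite Gaussians.

    One exponent ``alpha`` carries every Hermite function with angular index
    0..L_set, so a set with L_set = 2 holds 1 s + 3 p + 6 d = 10 functions.
    """

    alpha: float
    L_set: int

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"auxiliary exponent must be positive, got {self.alpha}")
        if self.L_set % 2 != 0 or not (0 <= self.L_set <= 6):
            raise ValueError(f"set angularity must be even in 0..6, got {self.L_set}")

    @property
    def n_functions(self) -> int:
        L = self.L_set
        return (L + 1) * (L + 2) * (L + 3) // 6


@dataclass(frozen=True)
class AtomicAuxBasis:
    """Auxiliary basis of one element: shared-exponent Hermite sets plus generator metadata.

    Sets are ordered from highest to lowest exponent and consecutive exponents
    form a geometric progression with ratio ``beta``.
    """

    element: str
    sets: tuple[HermiteAuxSet, ...]
    n: int | None = None
    beta: float | None = None
    alpha0: float | None = None
    lmax: int | None = None

    def __post_init__(self) -> None:
        if len(self.sets) < 1:
            raise ValueError("an auxiliary basis needs at least one set")
        alphas = [s.alpha for s in self.sets]
        if any(a <= b for a, b in zip(alphas, alphas[1:])):
            raise ValueError("auxiliary sets must be strictly descending in exponent")
        if self.beta is not None and len(alphas) > 1:
            ratios = np.array(alphas[:-1]) / np.array(alphas[1:])
            if not np.allclose(ratios, self.beta, rtol=1e-12, atol=0.0):
                raise ValueError("consecutive exponent ratios do not match beta")

    @property
    def alphas(self) -> np.ndarray:
        return np.array([s.alpha for s in self.sets])

    @property
    def n_alpha(self) -> int:
        """Number of exponents, i.e. number of auxiliary function sets."""
        return len(self.sets)

    @property
    def alpha_top(self) -> float:
        """The highest (first) exponent of the basis."""
        return self.sets[0].alpha

    @property
    def n_functions(self) -> int:
        return sum(s.n_functions for s in self.sets)


@dataclass(frozen=True)
class Molecule:
    """A molecular geometry: element symbols and Cartesian positions in bohr."""

    symbols: tuple[str, ...]
    coordinates: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (len(self.symbols), 3):
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if len(self.symbols) < 1:
            raise ValueError("a molecule needs at least one atom")
        for i in range(len(self.symbols)):
            for j in range(i + 1, len(self.symbols)):
                if np.array_equal(coords[i], coords[j]):
                    raise ValueError(f"atoms {i} and {j} exactly coincide")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


# ----------------------------------------------------------------------------
# orbital basis parsing / writing
# ----------------------------------------------------------------------------


def _float(token: str, lineno: int) -> float:
    try:
        return float(token.replace("D", "E").replace("d", "e"))
    except ValueError:
        raise BasisParseError(f"line {lineno}: cannot parse number {token!r}") from None


def _parse_gaussian_text(text: str) -> AtomicOrbitalBasis:
    lines = text.splitlines()
    element: str | None = None
    shells: list[ContractedShell] = []
    i = 0
    # skip leading blank/comment lines
    while i < len(lines) and (not lines[i].strip() or lines[i].lstrip().startswith("!")):
        i += 1
    if i >= len(lines):
        raise BasisParseError("empty basis block")
    head = lines[i].split()
    element = head[0].capitalize()
    i += 1
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("!"):
            i += 1
            continue
        if line.startswith("****"):
            break
        parts = line.split()
        label = parts[0].upper()
        if label == "SP":
            raise BasisParseError(f"line {i + 1}: composite SP shells are not supported")
        if label not in SHELL_LABELS:
            raise BasisParseError(f"line {i + 1}: unknown shell label {parts[0]!r}")
        if len(parts) < 2:
            raise BasisParseError(f"line {i + 1}: shell header needs a primitive count")
        l = SHELL_LABELS.index(label)
        nprim = int(parts[1])
        prims = []
        for k in range(nprim):
            i += 1
            if i >= len(lines) or not lines[i].strip():
                raise BasisParseError(f"line {i + 1}: expected {nprim} primitive lines")
            toks = lines[i].split()
            if len(toks) < 2:
                raise BasisParseError(f"line {i + 1}: expected exponent and coefficient")
            zeta = _float(toks[0], i + 1)
            coef = _float(toks[1], i + 1)
            if zeta <= 0:
                raise BasisParseError(f"line {i + 1}: non-positive exponent {zeta}")
            prims.append(PrimitiveGaussian(zeta, coef))
        shells.append(ContractedShell(l, tuple(prims)))
        i += 1
    if not shells:
        raise BasisParseError("no shells found in basis block")
    return AtomicOrbitalBasis(element, tuple(shells))


def _parse_json_obs(text: str) -> AtomicOrbitalBasis:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BasisParseError(f"invalid JSON: {exc}") from None
    try:
        shells = []
        for sh in obj["shells"]:
            prims = []
            for p in sh["primitives"]:
                zeta = float(p["exponent"])
                if zeta <= 0:
                    raise BasisParseError(f"non-positive exponent {zeta}")
                prims.append(PrimitiveGaussian(zeta, float(p.get("coefficient", 1.0))))
            shells.append(ContractedShell(int(sh["l"]), tuple(prims)))
        return AtomicOrbitalBasis(str(obj["element"]), tuple(shells))
    except (KeyError, TypeError) as exc:
        raise BasisParseError(f"malformed JSON basis object: {exc}") from None


def parse_orbital_basis(text: str, dialect: str = "gaussian_text") -> AtomicOrbitalBasis:
    """Parse an orbital basis set from ``gaussian_text`` or ``json`` text."""
    if not text.strip():
        raise BasisParseError("empty input")
    if dialect == "gaussian_text":
        return _parse_gaussian_text(text)
    if dialect == "json":
        return _parse_json_obs(text)
    raise ValueError(f"unsupported dialect {dialect!r}")


def write_orbital_basis(obs: AtomicOrbitalBasis, dialect: str = "gaussian_text") -> str:
    """Serialize an orbital basis; inverse of :func:`parse_orbital_basis`."""
    if dialect == "gaussian_text":
        out = [f"{obs.element} 0"]
        for sh in obs.shells:
            out.append(f"{SHELL_LABELS[sh.l]} {len(sh.primitives)} 1.00")
            for p in sh.primitives:
                out.append(f"  {p.exponent!r:>24} {p.coefficient!r:>24}")
        out.append("****")
        return "\n".join(out) + "\n"
    if dialect == "json":
        obj = {
            "element": obs.element,
            "shells": [
                {
                    "l": sh.l,
                    "primitives": [
                        {"exponent": p.exponent, "coefficient": p.coefficient}
                        for p in sh.primitives
                    ],
                }
                for sh in obs.shells
            ],
        }
        return json.dumps(obj, indent=1)
    raise ValueError(f"unsupported dialect {dialect!r}")


# ----------------------------------------------------------------------------
# auxiliary basis parsing / writing
# ----------------------------------------------------------------------------


def write_aux_basis(aux: AtomicAuxBasis, dialect: str = "demon_text") -> str:
    """Serialize an auxiliary basis.

    The ``demon_text`` layout is one header line
    ``ELEMENT GEN-Xn beta=B alpha0=A lmax=L`` followed by one
    ``k  L_set  alpha`` line per set in descending-exponent order.
    """
    if dialect == "demon_text":
        tag = f"GEN-X{aux.n}" if aux.n is not None else "AUX"
        head = f"{aux.element} {tag}"
        if aux.beta is not None:
            head += f" beta={aux.beta!r}"
        if aux.alpha0 is not None:
            head += f" alpha0={aux.alpha0!r}"
        if aux.lmax is not None:
            head += f" lmax={aux.lmax}"
        out = [head]
        for k, s in enumerate(aux.sets, start=1):
            out.append(f"{k:4d} {s.L_set:3d} {s.alpha!r:>24}")
        return "\n".join(out) + "\n"
    if dialect == "json":
        obj = {
            "element": aux.element,
            "n": aux.n,
            "beta": aux.beta,
            "alpha0": aux.alpha0,
            "lmax": aux.lmax,
            "sets": [{"L": s.L_set, "alpha": s.alpha} for s in aux.sets],
        }
        return json.dumps(obj, indent=1)
    raise ValueError(f"unsupported dialect {dialect!r}")


def parse_aux_basis(text: str, dialect: str = "demon_text") -> AtomicAuxBasis:
    """Parse an auxiliary basis; inverse of :func:`write_aux_basis`."""
    if not text.strip():
        raise BasisParseError("empty input")
    if dialect == "demon_text":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = lines[0].split()
        element = head[0].capitalize()
        n = beta = alpha0 = lmax = None
        for tok in head[1:]:
            if tok.startswith("GEN-X"):
                n = int(tok[5:])
            elif tok.startswith("beta="):
                beta = float(tok[5:])
            elif tok.startswith("alpha0="):
                alpha0 = float(tok[7:])
            elif tok.startswith("lmax="):
                lmax = int(tok[5:])
        sets = []
        for lineno, ln in enumerate(lines[1:], start=2):
            toks = ln.split()
            if len(toks) != 3:
                raise BasisParseError(f"line {lineno}: expected 'k L alpha'")
            sets.append(HermiteAuxSet(_float(toks[2], lineno), int(toks[1])))
        return AtomicAuxBasis(element, tuple(sets), n=n, beta=beta, alpha0=alpha0, lmax=lmax)
    if dialect == "json":
        try:
            obj = json.loads(text)
            sets = tuple(HermiteAuxSet(float(s["alpha"]), int(s["L"])) for s in obj["sets"])
            return AtomicAuxBasis(
                str(obj["element"]),
                sets,
                n=obj.get("n"),
                beta=obj.get("beta"),
                alpha0=obj.get("alpha0"),
                lmax=obj.get("lmax"),
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise BasisParseError(f"malformed JSON aux basis: {exc}") from None
    raise ValueError(f"unsupported dialect {dialect!r}")


# ----------------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------------


def parse_molecule(text: str, units: str = "angstrom") -> Molecule:
    """Parse an XYZ geometry; positions are converted to bohr internally."""
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"unsupported units {units!r}")
    lines = text.splitlines()
    if not lines:
        raise BasisParseError("empty XYZ input")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise BasisParseError("first XYZ line must be the atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != natoms:
        raise BasisParseError(
            f"XYZ header declares {natoms} atoms but body has {len(body)} atom lines"
        )
    symbols, coords = [], []
    for lineno, ln in enumerate(body, start=3):
        toks = ln.split()
        if len(toks) < 4:
            raise BasisParseError(f"line {lineno}: expected 'symbol x y z'")
        symbols.append(toks[0].capitalize())
        coords.append([_float(t, lineno) for t in toks[1:4]])
    xyz = np.array(coords)
    if units == "angstrom":
        xyz = xyz * ANGSTROM_TO_BOHR
    return Molecule(tuple(symbols), xyz)


def write_molecule(mol: Molecule, units: str = "angstrom", comment: str = "") -> str:
    """Serialize a molecule to XYZ text."""
    if units == "angstrom":
        xyz = mol.coordinates / ANGSTROM_TO_BOHR
    elif units == "bohr":
        xyz = mol.coordinates
    else:
        raise ValueError(f"unsupported units {units!r}")
    out = [str(mol.n_atoms), comment]
    for sym, pos in zip(mol.symbols, xyz):
        x, y, z = (repr(float(v)) for v in pos)
        out.append(f"{sym:3s} {x:>22} {y:>22} {z:>22}")
    return "\n".join(out) + "\n"
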
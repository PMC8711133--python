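"""Readers and writers for the toolkit's plain-text formats.

Four families of files are supported:

* torsion-scan tables — whitespace-separated ``angle energy`` rows, the
  product of a QM dihedral scan.  The canonical dialect is degrees/hartree
  with ``#`` comments (what a quantum-chemistry scan emits); radians,
  kcal/mol and kJ/mol dialects are opt-in.
* Amber ``frcmod`` DIHE blocks, including the negative-PN continuation
  convention for multi-term dihedrals.
* GROMACS ``[ dihedrals ]`` proper-dihedral (function type 9) lines.
* PLUMED-style two-column free-energy (fes) tables and four-column HILLS
  logs (time, center, sigma, height).

All angles are wrapped into [-pi, pi) on input and all energies converted
to kcal/mol; distances to Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_PER_NM, HARTREE_TO_KCAL, KJ_PER_KCAL
from .model import DihedralSeries, DihedralTerm, TorsionProfile, wrap_angle

__all__ = [
    "ScanTableDialect",
    "FrcmodDiheRecord",
    "read_scan_table",
    "write_scan_table",
    "write_frcmod",
    "parse_frcmod",
    "write_gromacs_dihedrals",
    "parse_gromacs_dihedrals",
    "read_fes",
    "write_fes",
    "read_hills",
    "write_hills",
]

_ENERGY_FACTORS = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "kj/mol": 1.0 / KJ_PER_KCAL,
    "kj": 1.0 / KJ_PER_KCAL,
    "hartree": HARTREE_TO_KCAL,
}


@dataclass(frozen=True)
class ScanTableDialect:
    """Units and comment convention of a two-column scan table."""

    angle_unit: str = "degrees"      # "degrees" | "radians"
    energy_unit: str = "hartree"     # "hartree" | "kcal/mol" | "kJ/mol"
    comment_char: str = "#"

    def __post_init__(self):
        if self.angle_unit not in ("degrees", "radians"):
            raise ValueError(f"unknown angle unit {self.angle_unit!r}")
        if self.energy_unit.lower() not in _ENERGY_FACTORS:
            raise ValueError(f"unknown energy unit {self.energy_unit!r}")
        if len(self.comment_char) != 1:
            raise ValueError("comment_char must be a single character")

    @property
    def energy_factor(self) -> float:
        return _ENERGY_FACTORS[self.energy_unit.lower()]


#: Dialect for tables already in the toolkit's internal units.
RADIANS_KCAL = ScanTableDialect(angle_unit="radians", energy_unit="kcal/mol")


@dataclass(frozen=True)
class FrcmodDiheRecord:
    """One DIHE line: atom-type quartet, IDIVF, PK, PHASE (deg), PN."""

    quartet: tuple
    idivf: int
    pk: float
    phase_deg: float
    pn: int

    def __post_init__(self):
        if len(self.quartet) != 4 or any(len(t) > 2 or not t for t in self.quartet):
            raise ValueError(f"quartet must be four 1-2 character type labels, got {self.quartet}")
        if self.idivf < 1:
            raise ValueError("idivf must be a positive integer")
        if abs(self.pn) < 1:
            raise ValueError("|pn| must be >= 1")


def _data_lines(path, comment_char="#"):
    """Yield (line_number, stripped_text) for non-empty, non-comment lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.split(comment_char, 1)[0].strip()
            if text:
                yield lineno, text


def read_scan_table(path, dialect: ScanTableDialect = ScanTableDialect(),
                    label: str | None = None) -> TorsionProfile:
    """Read a two-column (angle, energy) table into a :class:`TorsionProfile`.

    Angles are wrapped to [-pi, pi) and sorted; energies are converted to
    kcal/mol.  Duplicate angles after wrapping (within 1e-9 rad) and
    non-finite energies are rejected.
    """
    angles, energies = [], []
    for lineno, text in _data_lines(path, dialect.comment_char):
        parts = text.split()
        try:
            a, e = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            raise ValueError(f"{path}: unparseable row at line {lineno}: {text!r}") from None
        if not math.isfinite(e):
            raise ValueError(f"{path}: non-finite energy at line {lineno}")
        angles.append(a)
        energies.append(e)
    if len(angles) == 0:
        raise ValueError(f"{path}: no data rows")
    if len(angles) < 4:
        raise ValueError(f"{path}: need at least 4 data rows, found {len(angles)}")

    angles = np.asarray(angles, dtype=float)
    if dialect.angle_unit == "degrees":
        angles = np.deg2rad(angles)
    angles = np.asarray(wrap_angle(angles), dtype=float)
    energies = np.asarray(energies, dtype=float) * dialect.energy_factor

    order = np.argsort(angles, kind="stable")
    angles, energies = angles[order], energies[order]
    dup = np.nonzero(np.diff(angles) < 1e-9)[0]
    if dup.size:
        raise ValueError(
            f"{path}: duplicate angle(s) after wrapping: "
            + ", ".join(f"{angles[i]:.9f}" for i in dup))
    return TorsionProfile(angles, energies, label=label or Path(path).stem)


def write_scan_table(profile: TorsionProfile, path,
                     dialect: ScanTableDialect = RADIANS_KCAL) -> None:
    """Write a profile as a two-column table in the given dialect."""
    angles = profile.angles
    if dialect.angle_unit == "degrees":
        angles = np.rad2deg(angles)
    energies = profile.energies / dialect.energy_factor
    with open(path, "w") as fh:
        fh.write(f"{dialect.comment_char} angle({dialect.angle_unit}) "
                 f"energy({dialect.energy_unit})\n")
        for a, e in zip(angles, energies):
            fh.write(f"{a:.17g} {e:.17g}\n")


# ---------------------------------------------------------------------------
# Amber frcmod DIHE block
# ---------------------------------------------------------------------------

def _normalize_quartet(quartet) -> tuple:
    if isinstance(quartet, str):
        quartet = tuple(quartet.split("-"))
    quartet = tuple(str(t) for t in quartet)
    if len(quartet) != 4:
        raise ValueError(f"atom-type quartet must have 4 labels, got {quartet}")
    for t in quartet:
        if not t or len(t) > 2:
            raise ValueError(f"atom-type label {t!r} must be 1-2 characters")
    return quartet


def write_frcmod(series: DihedralSeries, quartet, path,
                 title: str = "torsionkit dihedral parameters") -> None:
    """Write the series as an frcmod DIHE block for one atom-type quartet.

    Multi-term series use Amber's continuation convention: every record but
    the last carries a negative PN.  PK is written with 3 decimals and the
    phase with 1 decimal (degrees); IDIVF is always 1.
    """
    quartet = _normalize_quartet(quartet)
    name = "-".join(f"{t:<2}" for t in quartet)
    lines = [title, "", "DIHE"]
    nterms = len(series.terms)
    for i, t in enumerate(series.terms):
        pn = t.periodicity_n if i == nterms - 1 else -t.periodicity_n
        phase = math.degrees(t.phase_psi)
        lines.append(f"{name}   1   {t.amplitude_k:10.3f}   {phase:8.1f}   {pn:6.1f}")
    lines += ["", ""]
    Path(path).write_text("\n".join(lines))


def parse_frcmod(path):
    """Parse the first dihedral of an frcmod DIHE block.

    Returns ``(quartet, DihedralSeries)``.  PK is interpreted as amplitude
    times IDIVF (i.e. amplitude = PK / IDIVF); a chain of negative-PN
    records is folded into one multi-term series.  A chain left dangling at
    the end of the block is an error.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip().upper() == "DIHE")
    except StopIteration:
        raise ValueError(f"{path}: no DIHE block found") from None

    records = []
    for ln in lines[start + 1:]:
        if not ln.strip():
            break
        body = ln[:11]
        rest = ln[11:].split()
        quartet = tuple(t.strip() for t in body.split("-"))
        if len(quartet) != 4 or len(rest) < 4:
            raise ValueError(f"{path}: malformed DIHE record: {ln!r}")
        idivf = int(float(rest[0]))
        pk = float(rest[1])
        phase = float(rest[2])
        pn = int(round(float(rest[3])))
        records.append(FrcmodDiheRecord(quartet, idivf, pk, phase, pn))
    if not records:
        raise ValueError(f"{path}: empty DIHE block")

    terms = []
    quartet = records[0].quartet
    for rec in records:
        if rec.quartet != quartet:
            break
        terms.append(DihedralTerm(rec.pk / rec.idivf, abs(rec.pn),
                                  math.radians(rec.phase_deg)))
        if rec.pn > 0:
            return quartet, DihedralSeries(tuple(terms))
    raise ValueError(f"{path}: dangling negative-PN chain at end of DIHE block")


# ---------------------------------------------------------------------------
# GROMACS [ dihedrals ] function type 9
# ---------------------------------------------------------------------------

def write_gromacs_dihedrals(series: DihedralSeries, atom_indices) -> list:
    """Render the series as GROMACS proper-dihedral (funct 9) topology lines.

    One line per term: ``ai aj ak al 9 phase_deg k_kJ pn`` with the force
    constant converted to kJ/mol.  Zero-amplitude terms are kept explicit.
    """
    ai = tuple(int(i) for i in atom_indices)
    if len(ai) != 4:
        raise ValueError("need exactly 4 atom indices")
    lines = []
    for t in series.terms:
        k_kj = t.amplitude_k * KJ_PER_KCAL
        phase = math.degrees(t.phase_psi)
        lines.append(f"{ai[0]:5d} {ai[1]:5d} {ai[2]:5d} {ai[3]:5d}     9 "
                     f"{phase:.10g} {k_kj:.10g} {t.periodicity_n}")
    return lines


def parse_gromacs_dihedrals(lines):
    """Inverse of :func:`write_gromacs_dihedrals` on its own output.

    Returns ``(atom_indices, DihedralSeries)`` with amplitudes back in
    kcal/mol.
    """
    terms, indices = [], None
    for ln in lines:
        parts = ln.split()
        if not parts or parts[0].startswith(";"):
            continue
        if len(parts) < 8 or parts[4] != "9":
            raise ValueError(f"not a function-type-9 dihedral line: {ln!r}")
        idx = tuple(int(p) for p in parts[:4])
        if indices is None:
            indices = idx
        terms.append(DihedralTerm(float(parts[6]) / KJ_PER_KCAL,
                                  int(parts[7]),
                                  math.radians(float(parts[5]))))
    if not terms:
        raise ValueError("no dihedral lines found")
    return indices, DihedralSeries(tuple(terms))


# ---------------------------------------------------------------------------
# PLUMED-style fes and HILLS tables
# ---------------------------------------------------------------------------

def read_fes(path, distance_unit: str = "A", energy_unit: str = "kcal/mol"):
    """Read a two-column (z, W) free-energy table.

    Returns a :class:`torsionkit.binding.FreeEnergyProfile1D` with the grid
    in Angstrom (``distance_unit="nm"`` multiplies by 10) and W in kcal/mol
    (``energy_unit="kJ/mol"`` divides by 4.184).  The grid must be strictly
    increasing.
    """
    from .binding import FreeEnergyProfile1D  # local import, avoids a cycle

    z, w = [], []
    for lineno, text in _data_lines(path):
        parts = text.split()
        try:
            z.append(float(parts[0]))
            w.append(float(parts[1]))
        except (ValueError, IndexError):
            raise ValueError(f"{path}: unparseable row at line {lineno}: {text!r}") from None
    if len(z) < 4:
        raise ValueError(f"{path}: need at least 4 rows, found {len(z)}")
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError(f"{path}: grid must be strictly increasing")
    if distance_unit.lower() in ("nm",):
        z = z * ANGSTROM_PER_NM
    elif distance_unit.upper() not in ("A", "ANGSTROM"):
        raise ValueError(f"unknown distance unit {distance_unit!r}")
    w = w * _ENERGY_FACTORS[energy_unit.lower()]
    return FreeEnergyProfile1D(z, w)


def write_fes(profile, path) -> None:
    """Write a 1-D free-energy profile as a two-column table (A, kcal/mol)."""
    with open(path, "w") as fh:
        fh.write("# z(A) W(kcal/mol)\n")
        for z, w in zip(profile.z_grid, profile.W):
            fh.write(f"{z:.17g} {w:.17g}\n")


def read_hills(path):
    """Read a four-column HILLS table (time, center, sigma, height).

    Centers are wrapped to [-pi, pi); times must be strictly increasing.
    """
    from .metadyn import HillsLog  # local import, avoids a cycle

    cols = [[], [], [], []]
    for lineno, text in _data_lines(path):
        parts = text.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: need 4 columns at line {lineno}: {text!r}")
        try:
            for c, p in zip(cols, parts):
                c.append(float(p))
        except ValueError:
            raise ValueError(f"{path}: unparseable row at line {lineno}: {text!r}") from None
    if not cols[0]:
        raise ValueError(f"{path}: no data rows")
    times, centers, sigmas, heights = (np.asarray(c, dtype=float) for c in cols)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return HillsLog(times, np.asarray(wrap_angle(centers), dtype=float), sigmas, heights)


def write_hills(hills, path) -> None:
    """Write a HILLS log as a four-column table (time center sigma height)."""
    with open(path, "w") as fh:
        fh.write("# time center(rad) sigma(rad) height(kcal/mol)\n")
        for t, c, s, h in zip(hills.times, hills.centers, hills.sigmas, hills.heights):
            fh.write(f"{t:.17g} {c:.17g} {s:.17g} {h:.17g}\n")
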
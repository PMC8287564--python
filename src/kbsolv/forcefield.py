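"""Hydroxypropyl-beta-cyclodextrin topologies and the ADD parameter patch.

The ADD carbohydrate description modifies the CHARMM36 hydroxyl groups in
two ways: the hydroxyl hydrogen partial charge drops from 0.42 e to 0.33 e
(with the deficit redistributed so the molecule stays neutral), and the
Lennard-Jones epsilon values of hydroxyl O and H atoms are replaced by a
single set for both the glucopyranose and hydroxypropyl hydroxyls:

    variant            eps(O)_gluco  eps(H)_gluco  eps(O)_hp  eps(H)_hp
    original CHARMM36      0.804        0.192        0.636      0.192
    ADD                    0.450        0.120        0.450      0.120
                                                            [kJ/mol]

Sigma values are untouched, as are all bonded parameters.

Topologies live in a strict, documented subset of the GROMACS itp format:
``[ moleculetype ]``, ``[ atomtypes ]`` (type, epsilon kJ/mol, sigma nm),
``[ atoms ]`` (nr, name, type, charge e, group tag, bonded-O index or 0)
and ``[ variant ]``.  Epsilon is denormalized onto each atom at load so
the two CHARMM36 hydroxyl classes can coexist and be patched per class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "TopologySpec",
    "TopologyChange",
    "CHARMM36_EPSILON",
    "ADD_EPSILON",
    "HYDROXYL_H_CHARGE_CHARMM36",
    "HYDROXYL_H_CHARGE_ADD",
    "load_topology",
    "loads_topology",
    "write_topology",
    "dumps_topology",
    "apply_add_patch",
    "diff_topologies",
    "example_topology",
    "example_topology_path",
]

GROUP_TAGS = (
    "glucopyranose_hydroxyl_O",
    "glucopyranose_hydroxyl_H",
    "hydroxypropyl_hydroxyl_O",
    "hydroxypropyl_hydroxyl_H",
    "other",
)

#: Table of hydroxyl Lennard-Jones epsilon values, kJ/mol, keyed by
#: (moiety, element).
CHARMM36_EPSILON = {
    ("glucopyranose", "O"): 0.804,
    ("glucopyranose", "H"): 0.192,
    ("hydroxypropyl", "O"): 0.636,
    ("hydroxypropyl", "H"): 0.192,
}
ADD_EPSILON = {
    ("glucopyranose", "O"): 0.450,
    ("glucopyranose", "H"): 0.120,
    ("hydroxypropyl", "O"): 0.450,
    ("hydroxypropyl", "H"): 0.120,
}

HYDROXYL_H_CHARGE_CHARMM36 = 0.42
HYDROXYL_H_CHARGE_ADD = 0.33

_TAG_TO_EPS_KEY = {
    "glucopyranose_hydroxyl_O": ("glucopyranose", "O"),
    "glucopyranose_hydroxyl_H": ("glucopyranose", "H"),
    "hydroxypropyl_hydroxyl_O": ("hydroxypropyl", "O"),
    "hydroxypropyl_hydroxyl_H": ("hydroxypropyl", "H"),
}

NEUTRALITY_TOL = 1e-6  # e


@dataclass
class Atom:
    index: int  # 1-based, as in the file
    name: str
    type_: str
    charge: float  # e
    epsilon: float  # kJ/mol
    sigma: float  # nm
    group_tag: str = "other"
    bonded_to: int | None = None  # 1-based index of the bonded O for hydroxyl H

    def __post_init__(self) -> None:
        if self.group_tag not in GROUP_TAGS:
            raise ValueError(f"unknown group tag {self.group_tag!r}")
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("Lennard-Jones parameters must be positive")


@dataclass
class TopologySpec:
    """A molecule's atoms with per-atom charges and LJ parameters."""

    molecule_name: str
    atoms: list[Atom]
    variant: str = "original_charmm36"

    def __post_init__(self) -> None:
        if self.variant not in ("original_charmm36", "ADD"):
            raise ValueError(f"unknown variant {self.variant!r}")
        total = self.total_charge
        if abs(total) > NEUTRALITY_TOL:
            raise ValueError(
                f"molecule {self.molecule_name!r} is not neutral: total charge "
                f"{total:+.6f} e exceeds {NEUTRALITY_TOL} e"
            )
        index_set = {a.index for a in self.atoms}
        for a in self.atoms:
            if a.group_tag.endswith("hydroxyl_H"):
                if a.bonded_to is None or a.bonded_to not in index_set:
                    raise ValueError(
                        f"hydroxyl hydrogen {a.name!r} lacks a valid bonded-O index"
                    )
                partner = self.atom(a.bonded_to)
                if not partner.group_tag.endswith("hydroxyl_O"):
                    raise ValueError(
                        f"hydroxyl hydrogen {a.name!r} is bonded to {partner.name!r}, "
                        "which is not tagged as a hydroxyl oxygen"
                    )

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def atom(self, index: int) -> Atom:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(index)

    def atoms_with_tag(self, tag: str) -> list[Atom]:
        return [a for a in self.atoms if a.group_tag == tag]


@dataclass
class TopologyChange:
    index: int
    name: str
    field: str
    old: float
    new: float


def loads_topology(text: str) -> TopologySpec:
    """Parse the documented itp-like dialect from a string."""
    section = None
    molecule_name = None
    variant = "original_charmm36"
    types: dict[str, tuple[float, float]] = {}
    raw_atoms: list[tuple] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        fields = line.split()
        try:
            if section == "moleculetype":
                molecule_name = fields[0]
            elif section == "atomtypes":
                if len(fields) != 3:
                    raise ValueError("atomtypes line needs: type epsilon sigma")
                types[fields[0]] = (float(fields[1]), float(fields[2]))
            elif section == "atoms":
                if len(fields) != 6:
                    raise ValueError(
                        "atoms line needs: nr name type charge tag bonded_to"
                    )
                raw_atoms.append(
                    (int(fields[0]), fields[1], fields[2], float(fields[3]),
                     fields[4], int(fields[5]))
                )
            elif section == "variant":
                variant = fields[0]
            elif section is None:
                raise ValueError("content before any section header")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"topology parse error at line {lineno}: {exc}") from exc
    if molecule_name is None:
        raise ValueError("missing [ moleculetype ] section")
    if not raw_atoms:
        raise ValueError("missing [ atoms ] section")
    atoms = []
    for nr, name, type_, charge, tag, bonded in raw_atoms:
        if type_ not in types:
            raise ValueError(f"atom {name!r} references undeclared type {type_!r}")
        eps, sigma = types[type_]
        atoms.append(
            Atom(
                index=nr, name=name, type_=type_, charge=charge,
                epsilon=eps, sigma=sigma, group_tag=tag,
                bonded_to=bonded if bonded > 0 else None,
            )
        )
    return TopologySpec(molecule_name=molecule_name, atoms=atoms, variant=variant)


def load_topology(path) -> TopologySpec:
    """Load a topology file in the documented itp-like dialect."""
    return loads_topology(Path(path).read_text())


def dumps_topology(top: TopologySpec) -> str:
    """Serialize at fixed precision (charges 4 decimals, epsilon 3, sigma 4)
    so golden-file comparisons are byte-stable."""
    type_params: dict[str, tuple[float, float]] = {}
    for a in top.atoms:
        key = (round(a.epsilon, 3), round(a.sigma, 4))
        if a.type_ in type_params and type_params[a.type_] != key:
            raise ValueError(
                f"atoms of type {a.type_!r} carry inconsistent LJ parameters; "
                "cannot serialize a per-type nonbonded section"
            )
        type_params[a.type_] = key
    buf = io.StringIO()
    buf.write("; kbsolv topology dialect (strict itp subset)\n")
    buf.write("[ moleculetype ]\n")
    buf.write(f"{top.molecule_name}\n\n")
    buf.write("[ atomtypes ]\n; type  epsilon(kJ/mol)  sigma(nm)\n")
    for t, (eps, sig) in type_params.items():
        buf.write(f"{t:<8s} {eps:7.3f} {sig:8.4f}\n")
    buf.write("\n[ atoms ]\n; nr  name  type  charge(e)  tag  bonded_to\n")
    for a in top.atoms:
        buf.write(
            f"{a.index:4d} {a.name:<6s} {a.type_:<8s} {a.charge:9.4f} "
            f"{a.group_tag:<26s} {a.bonded_to or 0:4d}\n"
        )
    buf.write("\n[ variant ]\n")
    buf.write(f"{top.variant}\n")
    return buf.getvalue()


def write_topology(top: TopologySpec, path) -> None:
    Path(path).write_text(dumps_topology(top))


def apply_add_patch(top: TopologySpec, charge_map: dict[str, float] | None = None) -> TopologySpec:
    """Convert an original-CHARMM36 topology to the ADD description.

    Every hydroxyl hydrogen charge becomes 0.33 e.  Without a charge map
    the per-hydroxyl deficit (old H charge minus 0.33 e, i.e. +0.09 e for
    CHARMM36 hydroxyls) moves to the bonded hydroxyl oxygen -- the minimal
    neutrality-preserving redistribution.  A ``charge_map`` of atom name ->
    charge (e.g. transcribed from a published per-atom charge set)
    overrides the redistribution for the atoms it names.  Epsilon values
    of the four hydroxyl classes are set to the ADD table; sigma and all
    other atoms are untouched.  Refuses an already-ADD topology.
    """
    if top.variant == "ADD":
        raise ValueError("topology already carries the ADD variant; refusing to re-patch")
    atoms = [replace(a) for a in top.atoms]
    by_index = {a.index: a for a in atoms}

    for a in atoms:
        if a.group_tag.endswith("hydroxyl_H"):
            deficit = a.charge - HYDROXYL_H_CHARGE_ADD
            a.charge = HYDROXYL_H_CHARGE_ADD
            by_index[a.bonded_to].charge += deficit
    if charge_map:
        names = {a.name for a in atoms}
        unknown = set(charge_map) - names
        if unknown:
            raise ValueError(f"charge map names unknown atoms: {sorted(unknown)}")
        for a in atoms:
            if a.name in charge_map:
                a.charge = float(charge_map[a.name])

    # a type shared by hydroxyl and non-hydroxyl atoms would receive an
    # ambiguous epsilon; require dedicated hydroxyl types
    hydroxyl_types = {a.type_ for a in atoms if a.group_tag in _TAG_TO_EPS_KEY}
    for a in atoms:
        if a.group_tag not in _TAG_TO_EPS_KEY and a.type_ in hydroxyl_types:
            raise ValueError(
                f"atom type {a.type_!r} is shared between hydroxyl and "
                "non-hydroxyl atoms; cannot patch epsilon per class"
            )
    for a in atoms:
        key = _TAG_TO_EPS_KEY.get(a.group_tag)
        if key is not None:
            a.epsilon = ADD_EPSILON[key]

    return TopologySpec(molecule_name=top.molecule_name, atoms=atoms, variant="ADD")


def diff_topologies(a: TopologySpec, b: TopologySpec) -> list[TopologyChange]:
    """Per-atom field changes between two topologies with identical atom
    lists; used to verify a patch touches only what it claims."""
    if len(a.atoms) != len(b.atoms):
        raise ValueError("atom lists differ in length")
    changes = []
    for x, y in zip(a.atoms, b.atoms):
        if (x.index, x.name, x.type_) != (y.index, y.name, y.type_):
            raise ValueError(f"atom mismatch at index {x.index}: {x.name} vs {y.name}")
        for field_name in ("charge", "epsilon", "sigma"):
            old, new = getattr(x, field_name), getattr(y, field_name)
            if abs(old - new) > 1e-12:
                changes.append(TopologyChange(x.index, x.name, field_name, old, new))
    return changes


# ---------------------------------------------------------------------------
# bundled example


def _glucopyranose_unit(unit: int, start: int, hydroxypropyl: bool):
    """Atoms of one synthetic glucopyranose subunit (charges sum to zero).

    Ring/backbone charges follow CHARMM36-style carbohydrate groups; a
    2-hydroxypropyl chain replaces the C6 hydroxyl hydrogen on substituted
    units.  This is a synthetic stand-in for a real HPbCD topology (the
    published per-atom charge set is not reproduced here); it is
    structurally and electrostatically plausible, not crystallographic.
    """
    u = f"{unit}"
    atoms: list[tuple] = [
        # (name, type, charge, tag, bonded offset or None)
        (f"C1{u}", "CTg", 0.27, "other", None),
        (f"H1{u}", "HAg", 0.09, "other", None),
        (f"O5{u}", "OEg", -0.36, "other", None),
        (f"C4{u}", "CTg", 0.27, "other", None),
        (f"H4{u}", "HAg", 0.09, "other", None),
        (f"O4{u}", "OEg", -0.36, "other", None),
        (f"C2{u}", "CTg", 0.14, "other", None),
        (f"H2{u}", "HAg", 0.09, "other", None),
        (f"O2{u}", "OHg", -0.65, "glucopyranose_hydroxyl_O", None),
        (f"HO2{u}", "HOg", 0.42, "glucopyranose_hydroxyl_H", -1),
        (f"C3{u}", "CTg", 0.14, "other", None),
        (f"H3{u}", "HAg", 0.09, "other", None),
        (f"O3{u}", "OHg", -0.65, "glucopyranose_hydroxyl_O", None),
        (f"HO3{u}", "HOg", 0.42, "glucopyranose_hydroxyl_H", -1),
        (f"C5{u}", "CTg", -0.09, "other", None),
        (f"H5{u}", "HAg", 0.09, "other", None),
    ]
    if hydroxypropyl:
        atoms += [
            (f"C6{u}", "CTg", -0.18, "other", None),
            (f"H61{u}", "HAg", 0.09, "other", None),
            (f"H62{u}", "HAg", 0.09, "other", None),
            (f"O6{u}", "OEg", -0.36, "other", None),
            (f"C7{u}", "CTg", 0.18, "other", None),
            (f"H71{u}", "HAg", 0.09, "other", None),
            (f"H72{u}", "HAg", 0.09, "other", None),
            (f"C8{u}", "CTg", 0.14, "other", None),
            (f"H8{u}", "HAg", 0.09, "other", None),
            (f"O8{u}", "OHp", -0.65, "hydroxypropyl_hydroxyl_O", None),
            (f"HO8{u}", "HOp", 0.42, "hydroxypropyl_hydroxyl_H", -1),
            (f"C9{u}", "CTg", -0.27, "other", None),
            (f"H91{u}", "HAg", 0.09, "other", None),
            (f"H92{u}", "HAg", 0.09, "other", None),
            (f"H93{u}", "HAg", 0.09, "other", None),
        ]
    else:
        atoms += [
            (f"C6{u}", "CTg", 0.05, "other", None),
            (f"H61{u}", "HAg", 0.09, "other", None),
            (f"H62{u}", "HAg", 0.09, "other", None),
            (f"O6{u}", "OHg", -0.65, "glucopyranose_hydroxyl_O", None),
            (f"HO6{u}", "HOg", 0.42, "glucopyranose_hydroxyl_H", -1),
        ]
    out = []
    for k, (name, type_, charge, tag, bonded) in enumerate(atoms):
        idx = start + k
        out.append(
            Atom(
                index=idx, name=name, type_=type_, charge=charge,
                epsilon=_EXAMPLE_TYPES[type_][0], sigma=_EXAMPLE_TYPES[type_][1],
                group_tag=tag,
                bonded_to=idx - 1 if bonded == -1 else None,
            )
        )
    return out


_EXAMPLE_TYPES = {
    "CTg": (0.330, 0.3560),
    "HAg": (0.110, 0.2380),
    "OEg": (0.500, 0.3000),
    "OHg": (CHARMM36_EPSILON[("glucopyranose", "O")], 0.3029),
    "HOg": (CHARMM36_EPSILON[("glucopyranose", "H")], 0.0400),
    "OHp": (CHARMM36_EPSILON[("hydroxypropyl", "O")], 0.3029),
    "HOp": (CHARMM36_EPSILON[("hydroxypropyl", "H")], 0.0400),
}


def example_topology() -> TopologySpec:
    """Synthetic HPbCD-like topology: seven glucopyranose subunits, four of
    them carrying a 2-hydroxypropyl substitution, with CHARMM36-style
    hydroxyl charges (H = 0.42 e) and the original hydroxyl epsilon table.
    A stand-in for a published topology, for tests and demonstrations."""
    atoms: list[Atom] = []
    start = 1
    for unit in range(1, 8):
        block = _glucopyranose_unit(unit, start, hydroxypropyl=unit <= 4)
        atoms.extend(block)
        start += len(block)
    return TopologySpec(molecule_name="HPBCD_SYN", atoms=atoms, variant="original_charmm36")


def example_topology_path() -> Path:
    """Path of the bundled synthetic example topology file."""
    return Path(__file__).parent / "data" / "hpbcd_synthetic_charmm36.itp"
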
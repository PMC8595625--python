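"""Per-atom nonbonded parameters: charge, Lennard-Jones, generalized-Born radius/scale.

The built-in table is a compact, self-consistent synthetic parameter set — not a
force field. It covers the backbone, C-beta, and the polar/charged side-chain
atoms the synthetic fixtures use (Asp/Glu carboxylates, Lys ammonium, Arg
guanidinium, Ser/Thr hydroxyls, amides). Each residue's charges sum to its
formal charge. Real decompositions should supply a parameter CSV exported from
a proper topology.

CSV dialect: ``atom_name, residue_name, charge, lj_rmin_half, lj_epsilon,
gb_radius, gb_scale`` with ``residue_name = "*"`` as a wildcard fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError
from .structure import Structure

CSV_COLUMNS = ["atom_name", "residue_name", "charge", "lj_rmin_half",
               "lj_epsilon", "gb_radius", "gb_scale"]


@dataclass(frozen=True)
class AtomParams:
    """Nonbonded parameters of one atom type.

    charge in elementary charges; lj_rmin_half (Å) and lj_epsilon (kcal/mol)
    in the Rmin/2 convention; gb_radius the intrinsic Born radius (Å);
    gb_scale the dimensionless descreening scale factor.
    """

    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    gb_radius: float
    gb_scale: float

    def __post_init__(self):
        if self.lj_epsilon < 0:
            raise ParameterError(f"lj_epsilon must be ≥ 0, got {self.lj_epsilon}")
        if self.gb_radius <= 0:
            raise ParameterError(f"gb_radius must be > 0, got {self.gb_radius}")


# element-wise GB defaults (radius Å, descreening scale)
_GB = {"N": (1.55, 0.79), "O": (1.50, 0.85), "C": (1.70, 0.72),
       "H": (1.20, 0.85), "S": (1.80, 0.96)}

def _p(charge, rmin_half, eps, element) -> AtomParams:
    radius, scale = _GB[element]
    return AtomParams(charge, rmin_half, eps, radius, scale)


#: generic (any-residue) backbone + C-beta parameters; charges sum to zero.
_GENERIC = {
    "N":  _p(-0.42, 1.85, 0.20, "N"),
    "CA": _p(+0.12, 2.28, 0.06, "C"),
    "C":  _p(+0.52, 2.00, 0.07, "C"),
    "O":  _p(-0.52, 1.70, 0.12, "O"),
    "CB": _p(+0.30, 2.06, 0.08, "C"),
    "OXT": _p(-0.52, 1.70, 0.12, "O"),
    "H":  _p(+0.30, 0.22, 0.046, "H"),
    "HA": _p(+0.00, 1.32, 0.022, "H"),
}

#: side-chain overrides; per-residue side-chain charges sum to the formal charge.
_SPECIFIC = {
    # Asp: CB + CG + carboxylate, net −1
    ("ASP", "CB"): _p(-0.18, 2.06, 0.08, "C"),
    ("ASP", "CG"): _p(+0.62, 2.00, 0.07, "C"),
    ("ASP", "OD1"): _p(-0.72, 1.70, 0.12, "O"),
    ("ASP", "OD2"): _p(-0.72, 1.70, 0.12, "O"),
    # Glu, net −1
    ("GLU", "CB"): _p(-0.10, 2.06, 0.08, "C"),
    ("GLU", "CG"): _p(-0.08, 2.06, 0.08, "C"),
    ("GLU", "CD"): _p(+0.62, 2.00, 0.07, "C"),
    ("GLU", "OE1"): _p(-0.72, 1.70, 0.12, "O"),
    ("GLU", "OE2"): _p(-0.72, 1.70, 0.12, "O"),
    # Lys, net +1 on the ammonium end
    ("LYS", "CB"): _p(+0.00, 2.06, 0.08, "C"),
    ("LYS", "CG"): _p(+0.00, 2.06, 0.08, "C"),
    ("LYS", "CD"): _p(+0.00, 2.06, 0.08, "C"),
    ("LYS", "CE"): _p(+0.25, 2.06, 0.08, "C"),
    ("LYS", "NZ"): _p(+0.75, 1.85, 0.20, "N"),
    # Arg, net +1 spread over the guanidinium
    ("ARG", "CB"): _p(+0.00, 2.06, 0.08, "C"),
    ("ARG", "CG"): _p(+0.00, 2.06, 0.08, "C"),
    ("ARG", "CD"): _p(+0.10, 2.06, 0.08, "C"),
    ("ARG", "NE"): _p(-0.40, 1.85, 0.20, "N"),
    ("ARG", "CZ"): _p(+0.70, 2.00, 0.07, "C"),
    ("ARG", "NH1"): _p(+0.30, 1.85, 0.20, "N"),
    ("ARG", "NH2"): _p(+0.30, 1.85, 0.20, "N"),
    # Ser/Thr hydroxyls (neutral)
    ("SER", "CB"): _p(+0.25, 2.06, 0.08, "C"),
    ("SER", "OG"): _p(-0.65, 1.70, 0.12, "O"),
    ("SER", "HG"): _p(+0.40, 0.22, 0.046, "H"),
    ("THR", "CB"): _p(+0.25, 2.06, 0.08, "C"),
    ("THR", "OG1"): _p(-0.65, 1.70, 0.12, "O"),
    ("THR", "HG1"): _p(+0.40, 0.22, 0.046, "H"),
    ("THR", "CG2"): _p(+0.00, 2.06, 0.08, "C"),
    # Asn/Gln amides (neutral)
    ("ASN", "CB"): _p(+0.00, 2.06, 0.08, "C"),
    ("ASN", "CG"): _p(+0.55, 2.00, 0.07, "C"),
    ("ASN", "OD1"): _p(-0.55, 1.70, 0.12, "O"),
    ("ASN", "ND2"): _p(-0.60, 1.85, 0.20, "N"),
    ("ASN", "HD21"): _p(+0.30, 0.22, 0.046, "H"),
    ("ASN", "HD22"): _p(+0.30, 0.22, 0.046, "H"),
    ("GLN", "CB"): _p(+0.00, 2.06, 0.08, "C"),
    ("GLN", "CG"): _p(+0.00, 2.06, 0.08, "C"),
    ("GLN", "CD"): _p(+0.55, 2.00, 0.07, "C"),
    ("GLN", "OE1"): _p(-0.55, 1.70, 0.12, "O"),
    ("GLN", "NE2"): _p(-0.60, 1.85, 0.20, "N"),
    ("GLN", "HE21"): _p(+0.30, 0.22, 0.046, "H"),
    ("GLN", "HE22"): _p(+0.30, 0.22, 0.046, "H"),
}


class ParamTable:
    """Lookup of :class:`AtomParams` by (residue_name, atom_name) with wildcards."""

    def __init__(self, specific: dict[tuple[str, str], AtomParams] | None = None,
                 generic: dict[str, AtomParams] | None = None):
        self.specific = dict(specific or {})
        self.generic = dict(generic or {})

    def lookup(self, residue_name: str, atom_name: str) -> AtomParams:
        key = (residue_name.upper(), atom_name.upper())
        if key in self.specific:
            return self.specific[key]
        if atom_name.upper() in self.generic:
            return self.generic[atom_name.upper()]
        raise ParameterError(
            f"no parameters for atom {atom_name} of residue {residue_name}")

    def for_structure(self, structure: Structure) -> list[AtomParams]:
        return [self.lookup(a.residue_name, a.atom_name) for a in structure.atoms]

    # -- CSV round trip -----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParamTable":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"parameter CSV lacks columns: {missing}")
        specific, generic = {}, {}
        for row in df.itertuples(index=False):
            p = AtomParams(float(row.charge), float(row.lj_rmin_half),
                           float(row.lj_epsilon), float(row.gb_radius),
                           float(row.gb_scale))
            res = str(row.residue_name).strip().upper()
            name = str(row.atom_name).strip().upper()
            if res == "*":
                generic[name] = p
            else:
                specific[(res, name)] = p
        return cls(specific, generic)

    def to_csv(self, path: str | Path) -> None:
        rows = [{"atom_name": n, "residue_name": "*", "charge": p.charge,
                 "lj_rmin_half": p.lj_rmin_half, "lj_epsilon": p.lj_epsilon,
                 "gb_radius": p.gb_radius, "gb_scale": p.gb_scale}
                for n, p in sorted(self.generic.items())]
        rows += [{"atom_name": n, "residue_name": r, "charge": p.charge,
                  "lj_rmin_half": p.lj_rmin_half, "lj_epsilon": p.lj_epsilon,
                  "gb_radius": p.gb_radius, "gb_scale": p.gb_scale}
                 for (r, n), p in sorted(self.specific.items())]
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def default_params() -> ParamTable:
    """The built-in synthetic parameter table."""
    return ParamTable(dict(_SPECIFIC), dict(_GENERIC))
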
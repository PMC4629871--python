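"""Balanced anaerobic fermentation of sugar acids to acetate, bicarbonate and H2.

An uncharged C/H/O substrate (isosaccharinic acid C6H12O6, its five-carbon
xylo analogue C5H10O5, or any similar carbohydrate-derived acid) ferments as

    substrate + a H2O -> b CH3COO- + c HCO3- + d H2 + e H+

Conservation of C, H, O and charge gives four equations in five unknowns, so
one closure constraint is required to pin down the reaction.  The default
closure takes acetate and bicarbonate equimolar (b = c), which corresponds to
the classical anaerobic carbohydrate fermentation split of two thirds of the
substrate carbon to acetate and one third to bicarbonate.  All coefficients
are kept as exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .data_model import AnalyteSpec

__all__ = [
    "Reaction",
    "StoichiometryError",
    "balance_fermentation",
    "verify_balance",
    "predicted_products",
    "carbon_split",
]

#: element composition of each product species: (C, H, O, charge)
_PRODUCT_ATOMS = {
    "water": (0, 2, 1, 0),
    "acetate": (2, 3, 2, -1),
    "bicarbonate": (1, 1, 3, -1),
    "h2": (0, 2, 0, 0),
    "h+": (0, 1, 0, 1),
}


class StoichiometryError(ValueError):
    """Raised when no valid balanced reaction exists under the constraints."""


@dataclass(frozen=True)
class Reaction:
    """A balanced fermentation with exact rational coefficients.

    ``a``..``e`` are the coefficients of H2O, acetate, bicarbonate, H2 and H+
    per mole of substrate.
    """

    substrate: AnalyteSpec
    a: Fraction  # H2O
    b: Fraction  # acetate
    c: Fraction  # bicarbonate
    d: Fraction  # H2
    e: Fraction  # H+

    @property
    def coefficients(self) -> dict[str, Fraction]:
        return {"water": self.a, "acetate": self.b, "bicarbonate": self.c,
                "h2": self.d, "h+": self.e}

    def __str__(self) -> str:
        def fmt(x: Fraction) -> str:
            return f"{float(x):.2f}".rstrip("0").rstrip(".") if x.denominator != 1 else str(x)

        return (
            f"{self.substrate.name} + {fmt(self.a)} H2O -> "
            f"{fmt(self.b)} CH3COO- + {fmt(self.c)} HCO3- + "
            f"{fmt(self.d)} H2 + {fmt(self.e)} H+"
        )


def _substrate_atoms(substrate: AnalyteSpec) -> tuple[int, int, int]:
    extra = set(substrate.formula) - {"C", "H", "O"}
    if extra:
        raise StoichiometryError(
            f"substrate {substrate.name} contains elements beyond C/H/O: {sorted(extra)}"
        )
    if substrate.charge != 0:
        raise StoichiometryError(f"substrate {substrate.name} must be uncharged")
    return (
        substrate.formula.get("C", 0),
        substrate.formula.get("H", 0),
        substrate.formula.get("O", 0),
    )


def balance_fermentation(
    substrate: AnalyteSpec,
    closure: str = "equimolar",
    fixed_acetate: Fraction | float | None = None,
) -> Reaction:
    """Solve the conservation system for the fermentation coefficients.

    Closures:

    * ``"equimolar"`` (default) — acetate and bicarbonate equimolar (b = c);
      reproduces the textbook 2:1 acetate:bicarbonate carbon split.
    * ``"max-h2"`` — all substrate carbon oxidised to bicarbonate (b = 0),
      the hydrogen-maximising limit.
    * ``"fixed-acetate"`` — acetate coefficient imposed via ``fixed_acetate``.

    Raises :class:`StoichiometryError` for carbon-free substrates or a closure
    that forces any coefficient negative.
    """
    x, y, z = (Fraction(v) for v in _substrate_atoms(substrate))
    if x == 0:
        raise StoichiometryError(f"substrate {substrate.name} contains no carbon")

    # carbon: x = 2b + c, together with the closure, fixes b and c
    if closure == "equimolar":
        b = x / 3
    elif closure == "max-h2":
        b = Fraction(0)
    elif closure == "fixed-acetate":
        if fixed_acetate is None:
            raise StoichiometryError("fixed-acetate closure requires fixed_acetate")
        b = Fraction(fixed_acetate)
    else:
        raise StoichiometryError(f"unknown closure {closure!r}")

    c = x - 2 * b
    e = b + c  # charge: e - b - c = 0
    a = 2 * b + 3 * c - z  # oxygen: z + a = 2b + 3c
    d = (y + 2 * a - 3 * b - c - e) / 2  # hydrogen: y + 2a = 3b + c + 2d + e

    rxn = Reaction(substrate, a=a, b=b, c=c, d=d, e=e)
    for name, value in rxn.coefficients.items():
        if value < 0:
            raise StoichiometryError(
                f"closure {closure!r} makes the {name} coefficient negative "
                f"({value}) for {substrate.name}"
            )
    return rxn


def verify_balance(reaction: Reaction) -> dict[str, Fraction]:
    """Element and charge residuals (products minus reactants); all zero for
    a balanced reaction.  Computed by direct atom counting, exactly."""
    x, y, z = (Fraction(v) for v in _substrate_atoms(reaction.substrate))
    residuals = {"C": -x, "H": -y, "O": -z, "charge": Fraction(0)}
    residuals["H"] -= 2 * reaction.a  # water is a reactant
    residuals["O"] -= reaction.a
    for species in ("acetate", "bicarbonate", "h2", "h+"):
        coeff = reaction.coefficients[species]
        n_c, n_h, n_o, chg = _PRODUCT_ATOMS[species]
        residuals["C"] += coeff * n_c
        residuals["H"] += coeff * n_h
        residuals["O"] += coeff * n_o
        residuals["charge"] += coeff * chg
    return residuals


def predicted_products(reaction: Reaction, substrate_mmol: float) -> dict[str, float]:
    """Product amounts (mmol) from fermenting ``substrate_mmol`` of substrate."""
    if substrate_mmol < 0:
        raise StoichiometryError("substrate amount must be non-negative")
    return {name: float(coeff) * substrate_mmol for name, coeff in reaction.coefficients.items()}


def carbon_split(reaction: Reaction) -> tuple[Fraction, Fraction]:
    """Fractions of substrate carbon routed to acetate and to bicarbonate.

    Acetate carries 2 carbons per molecule, bicarbonate 1; the two fractions
    sum to 1 for any reaction conserving carbon.
    """
    x = Fraction(reaction.substrate.n_carbon)
    if x == 0:
        raise StoichiometryError("substrate contains no carbon")
    return (2 * reaction.b / x, reaction.c / x)
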
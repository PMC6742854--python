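"""In-silico cleavage, search-configuration enumeration and mass arithmetic.

The cleavage model matches the search strategy used against the chimeric
database: one rule per search, cutting at the carboxyl or the amino
extremity of a single residue species (L and I merged, hence 19 residues
and 2 × 19 = 38 search configurations per sample), with a missed-cleavage
budget (default: at most one missed cleavage, the trypsin setting).

Monoisotopic masses come from the standard residue-mass table
(pyteomics); modification deltas default to the Unimod monoisotopic
values for carbamidomethyl (C, fixed), oxidation (M, variable) and the
Lys->pyrrolysine delta (variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from pyteomics import mass as _pt_mass

from .translation import STOP_SUBSTITUTIONS, collapse_il

WATER_MONO = 18.010565

#: Unimod monoisotopic deltas, Da.
CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.99491
LYS_TO_PYRLYS = 109.05276


class DigestError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageRule:
    """Cut at one residue species (I≡L), on one side, with a missed budget."""

    residue: str
    side: str  # 'carboxyl' or 'amino'
    max_missed: int = 1

    def __post_init__(self) -> None:
        r = collapse_il(self.residue.upper())
        object.__setattr__(self, "residue", r)
        if r not in STOP_SUBSTITUTIONS:
            raise ValueError(
                f"residue must be in the 19-letter merged alphabet, got {self.residue!r}"
            )
        if self.side not in ("carboxyl", "amino"):
            raise ValueError("side must be 'carboxyl' or 'amino'")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def matches(self, aa: str) -> bool:
        return collapse_il(aa.upper()) == self.residue

    @classmethod
    def parse(cls, text: str, max_missed: int = 1) -> "CleavageRule":
        """Parse 'K:carboxyl' / 'R:amino' style rule strings."""
        residue, _, side = text.partition(":")
        return cls(residue=residue, side=side or "carboxyl", max_missed=max_missed)


@dataclass(frozen=True)
class Fragment:
    """A digestion product with its 0-based offset in the parent."""

    offset: int
    sequence: str
    missed: int

    def __len__(self) -> int:
        return len(self.sequence)


def cut_positions(peptide: str, rule: CleavageRule) -> List[int]:
    """Internal cut points (0 < c < len): carboxyl cuts after the residue,
    amino cuts before it; cuts coinciding with a terminus are no-ops."""
    n = len(peptide)
    cuts = []
    for i, aa in enumerate(peptide):
        if not rule.matches(aa):
            continue
        c = i + 1 if rule.side == "carboxyl" else i
        if 0 < c < n:
            cuts.append(c)
    return sorted(set(cuts))


def digest(peptide: str, rule: CleavageRule) -> List[Fragment]:
    """All fragments with at most ``rule.max_missed`` missed cleavages.

    Fragments are maximal runs between cut points, merged across up to
    ``max_missed`` adjacent cuts; ordered by offset, then length.
    """
    if not peptide:
        raise DigestError("empty peptide")
    bounds = [0] + cut_positions(peptide, rule) + [len(peptide)]
    frags = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + rule.max_missed, len(bounds))):
            frags.append(
                Fragment(
                    offset=bounds[i],
                    sequence=peptide[bounds[i] : bounds[j]],
                    missed=j - i - 1,
                )
            )
    frags.sort(key=lambda f: (f.offset, len(f.sequence)))
    return frags


@dataclass(frozen=True)
class SearchConfig:
    rule: CleavageRule
    label: str


def enumerate_search_configs(max_missed: int = 1) -> List[SearchConfig]:
    """The 38 per-sample configurations: each of the 19 merged residues at
    each extremity, residues alphabetical, carboxyl before amino."""
    configs = []
    for residue in STOP_SUBSTITUTIONS:
        for side in ("carboxyl", "amino"):
            rule = CleavageRule(residue, side, max_missed)
            configs.append(SearchConfig(rule=rule, label=f"{residue}:{side}"))
    return configs


@dataclass(frozen=True)
class ModificationSet:
    """Fixed and variable (residue, monoisotopic delta) modifications."""

    fixed: Tuple[Tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    variable: Tuple[Tuple[str, float], ...] = (
        ("M", OXIDATION),
        ("K", LYS_TO_PYRLYS),
    )

    def fixed_mods_for(self, peptide: str) -> List[Tuple[int, float]]:
        """(position, delta) pairs for every fixed-modification site."""
        deltas = dict(self.fixed)
        return [
            (i, deltas[aa])
            for i, aa in enumerate(peptide.upper())
            if aa in deltas
        ]


def monoisotopic_mass(
    peptide: str, mods: Sequence[Tuple[int, float]] = ()
) -> float:
    """Peptide monoisotopic mass: residue masses + water + mod deltas.

    Lowercase (stop-translated) letters are normalised to their amino
    acid before lookup.
    """
    if not peptide:
        raise ValueError("empty peptide")
    total = WATER_MONO
    for i, aa in enumerate(peptide.upper()):
        try:
            total += _pt_mass.std_aa_mass[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid {aa!r} at position {i + 1}") from None
    for _pos, delta in mods:
        total += delta
    return total


def ppm_difference(observed: float, expected: float) -> float:
    """Signed mass deviation in parts per million."""
    if expected <= 0:
        raise ValueError("expected mass must be positive")
    return 1e6 * (observed - expected) / expected
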
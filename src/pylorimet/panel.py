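"""Targeted metabolite panel: nomenclature, class bookkeeping, target values.

The panel models a Biocrates-style broad targeted assay of 408 metabolites
across eleven classes: acylcarnitines (AC), amino acids (AA), biogenic
amines (BA), phosphatidylcholines (PC), lysophosphatidylcholines (LPC),
sphingomyelins (SM), ceramides (Cer), summed hexoses (HEX), cholesterol
esters (CE), diglycerides (DG) and triglycerides (TG).

Lipid species are written ``CLASS(X:Y)`` where X is the total number of acyl
carbon atoms and Y the number of double bonds.  Ether-linked species carry an
``-O`` suffix on the class prefix (``PC-O(36:4)``); hydroxylated and
dicarboxyl acylcarnitines carry ``-OH`` / ``-DC`` inside the parentheses
(``AC(16:0-OH)``).  Amino acids, biogenic amines and the summed hexose
measure use plain names (``Histidine``, ``Taurine``, ``Hexoses``).

Each panel entry also carries a reference (target) concentration ``TV_m`` in
µM for the medium-level quality-control sample; plate correction factors are
defined against it.  The bundled default panel ships *synthetic* target
values and placeholder species names that match the published per-class
counts; a real kit export in the same TSV layout can be loaded in its place.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "MetClass",
    "Modifier",
    "ParsedName",
    "PanelEntry",
    "PanelDefinition",
    "PanelError",
    "parse_metabolite_name",
    "format_metabolite_name",
    "panel_total",
    "default_panel",
    "load_panel",
    "write_panel",
]


class PanelError(ValueError):
    """Raised for malformed metabolite names or inconsistent panel files."""


class MetClass(str, Enum):
    AC = "AC"
    AA = "AA"
    BA = "BA"
    PC = "PC"
    LPC = "LPC"
    SM = "SM"
    Cer = "Cer"
    HEX = "HEX"
    CE = "CE"
    DG = "DG"
    TG = "TG"


class Modifier(str, Enum):
    none = "none"
    ether = "O"
    hydroxyl = "OH"
    dicarboxyl = "DC"


#: standard proteinogenic amino acids measured by the assay plus urea-cycle
#: intermediates, 21 in total
AMINO_ACIDS = (
    "Alanine", "Arginine", "Asparagine", "Aspartate", "Citrulline",
    "Glutamine", "Glutamate", "Glycine", "Histidine", "Isoleucine",
    "Leucine", "Lysine", "Methionine", "Ornithine", "Phenylalanine",
    "Proline", "Serine", "Threonine", "Tryptophan", "Tyrosine", "Valine",
)

#: 21 biogenic amines; placeholder selection of commonly assayed analytes
BIOGENIC_AMINES = (
    "ADMA", "SDMA", "alpha-Aminoadipate", "Betaine", "Carnosine", "Choline",
    "Creatinine", "Dopamine", "Histamine", "Kynurenine", "Methioninesulfoxide",
    "Putrescine", "Sarcosine", "Serotonin", "Spermidine", "Spermine",
    "Taurine", "TMAO", "trans-4-Hydroxyproline", "Tryptamine", "Tyramine",
)

HEXOSES_NAME = "Hexoses"

_LIPID_PREFIXES = ("LPC", "PC", "SM", "Cer", "CE", "DG", "TG", "AC")
_LIPID_RE = re.compile(
    r"^(?P<prefix>LPC|PC|SM|Cer|CE|DG|TG|AC)"
    r"(?P<ether>-O)?"
    r"\((?P<x>\d+):(?P<y>\d+)(?P<mod>-OH|-DC)?\)$"
)


@dataclass(frozen=True)
class ParsedName:
    """Decomposed metabolite name (without a target value)."""

    met_class: MetClass
    carbons: int | None = None
    double_bonds: int | None = None
    modifier: Modifier = Modifier.none


@dataclass(frozen=True)
class PanelEntry:
    """One metabolite of the panel with its QC2 target value TV_m (µM)."""

    name: str
    met_class: MetClass
    carbons: int | None
    double_bonds: int | None
    modifier: Modifier
    target_value_uM: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_value_uM) or self.target_value_uM <= 0:
            raise PanelError(
                f"{self.name}: target_value_uM must be positive, got "
                f"{self.target_value_uM!r}"
            )


def parse_metabolite_name(name: str) -> ParsedName:
    """Decompose a metabolite name into class, chain composition and modifier.

    Lipids follow ``CLASS(X:Y)`` with optional ``-O`` ether prefix suffix and
    ``-OH``/``-DC`` chain modifiers; amino acids, biogenic amines and
    ``Hexoses`` are recognised by membership in the bundled name lists.

    Raises
    ------
    PanelError
        If the name is empty, uses unknown class prefixes, or has malformed
        ``X:Y`` syntax.
    """
    if not name:
        raise PanelError("empty metabolite name")
    if name == HEXOSES_NAME:
        return ParsedName(MetClass.HEX)
    if name in AMINO_ACIDS:
        return ParsedName(MetClass.AA)
    if name in BIOGENIC_AMINES:
        return ParsedName(MetClass.BA)
    m = _LIPID_RE.match(name)
    if m is None:
        # Distinguish "looks like a lipid but malformed" from "unknown name"
        prefix = next((p for p in _LIPID_PREFIXES if name.startswith(p)), None)
        if prefix is not None:
            raise PanelError(
                f"malformed lipid name {name!r}: expected "
                f"'{prefix}(X:Y)' with integer X, Y"
            )
        raise PanelError(f"unknown metabolite name {name!r}")
    prefix = m.group("prefix")
    if m.group("ether"):
        if m.group("mod"):
            raise PanelError(f"{name!r}: ether and chain modifier are exclusive")
        modifier = Modifier.ether
    elif m.group("mod") == "-OH":
        modifier = Modifier.hydroxyl
    elif m.group("mod") == "-DC":
        modifier = Modifier.dicarboxyl
    else:
        modifier = Modifier.none
    return ParsedName(
        met_class=MetClass[prefix],
        carbons=int(m.group("x")),
        double_bonds=int(m.group("y")),
        modifier=modifier,
    )


def format_metabolite_name(parsed: ParsedName, plain_name: str | None = None) -> str:
    """Inverse of :func:`parse_metabolite_name`.

    For AA/BA entries the plain name carries the identity and must be given.
    """
    if parsed.met_class is MetClass.HEX:
        return HEXOSES_NAME
    if parsed.met_class in (MetClass.AA, MetClass.BA):
        if plain_name is None:
            raise PanelError(f"{parsed.met_class.value} entries need a plain name")
        return plain_name
    if parsed.carbons is None or parsed.double_bonds is None:
        raise PanelError("lipid entries need carbons and double_bonds")
    prefix = parsed.met_class.value
    xy = f"{parsed.carbons}:{parsed.double_bonds}"
    if parsed.modifier is Modifier.ether:
        return f"{prefix}-O({xy})"
    if parsed.modifier is Modifier.hydroxyl:
        return f"{prefix}({xy}-OH)"
    if parsed.modifier is Modifier.dicarboxyl:
        return f"{prefix}({xy}-DC)"
    return f"{prefix}({xy})"


@dataclass
class PanelDefinition:
    """A validated list of panel entries with per-class tallies."""

    entries: list[PanelEntry]
    class_counts: dict[MetClass, int] = field(init=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate panel entries: {dupes}")
        self.class_counts = {}
        for e in self.entries:
            self.class_counts[e.met_class] = self.class_counts.get(e.met_class, 0) + 1

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def target_values(self) -> dict[str, float]:
        return {e.name: e.target_value_uM for e in self.entries}

    def get(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def panel_total(panel: PanelDefinition) -> int:
    """Number of metabolites on the panel (equals the class-count sum)."""
    total = sum(panel.class_counts.values())
    assert total == len(panel.entries)
    return total


def _entry(name: str, tv: float) -> PanelEntry:
    p = parse_metabolite_name(name)
    return PanelEntry(name, p.met_class, p.carbons, p.double_bonds, p.modifier, tv)


def _take(candidates: Iterable[str], k: int) -> list[str]:
    out = []
    for name in candidates:
        if name not in out:
            out.append(name)
        if len(out) == k:
            return out
    raise PanelError(f"candidate pool exhausted: needed {k}, got {len(out)}")


def _lipid_grid(prefix: str, xs: range, ys: range, suffix: str = "") -> list[str]:
    return [f"{prefix}({x}:{y}{suffix})" for x in xs for y in ys]


# Plausible reference-concentration ranges (µM) per class used to draw the
# synthetic bundled target values; whole blood, order-of-magnitude only.
_TV_RANGE = {
    MetClass.AC: (0.05, 10.0),
    MetClass.AA: (20.0, 500.0),
    MetClass.BA: (0.1, 50.0),
    MetClass.PC: (0.5, 80.0),
    MetClass.LPC: (0.2, 40.0),
    MetClass.SM: (1.0, 60.0),
    MetClass.Cer: (0.1, 5.0),
    MetClass.HEX: (2000.0, 5000.0),
    MetClass.CE: (10.0, 300.0),
    MetClass.DG: (0.5, 30.0),
    MetClass.TG: (1.0, 100.0),
}


def default_panel(seed: int = 12345) -> PanelDefinition:
    """Bundled 408-metabolite panel with synthetic species names and TV_m.

    The per-class composition matches the kit: 55 AC, 21 AA, 21 BA,
    196 glycerophospholipids (24 LPC + 172 PC), 40 sphingolipids
    (31 SM + 9 Cer), 1 summed hexose measure, 14 CE and 60 glycerides
    (18 DG + 42 TG).  Species names not printed in the source material are
    deterministic placeholders on realistic carbon/double-bond grids; target
    values are synthetic draws, log-uniform within a realistic per-class
    concentration range.
    """
    names: list[str] = []
    # acylcarnitines: 45 plain + 6 hydroxyl + 4 dicarboxyl = 55
    names += _take(_lipid_grid("AC", range(2, 20), range(0, 3)), 45)
    names += _take(_lipid_grid("AC", range(4, 18, 2), range(0, 1), "-OH"), 6)
    names += _take(_lipid_grid("AC", range(3, 12, 2), range(0, 1), "-DC"), 4)
    names += list(AMINO_ACIDS)          # 21
    names += list(BIOGENIC_AMINES)      # 21
    names += _take(_lipid_grid("LPC", range(14, 26), range(0, 2)), 24)
    # phosphatidylcholines: 119 diacyl + 53 ether = 172
    names += _take(_lipid_grid("PC", range(28, 45), range(0, 7)), 119)
    names += _take(["PC-O(36:4)"] + _lipid_grid("PC-O", range(28, 45), range(0, 7)), 53)
    names += _take(_lipid_grid("SM", range(30, 41), range(0, 3)), 31)
    names += _take(_lipid_grid("Cer", range(34, 43), range(1, 2)), 9)
    names += [HEXOSES_NAME]
    names += _take(_lipid_grid("CE", range(14, 21), range(0, 2)), 14)
    names += _take(_lipid_grid("DG", range(30, 39), range(0, 2)), 18)
    names += _take(_lipid_grid("TG", range(44, 58), range(0, 3)), 42)

    rng = np.random.default_rng(seed)
    entries = []
    for name in names:
        parsed = parse_metabolite_name(name)
        lo, hi = _TV_RANGE[parsed.met_class]
        tv = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        entries.append(
            PanelEntry(name, parsed.met_class, parsed.carbons,
                       parsed.double_bonds, parsed.modifier, round(tv, 4))
        )
    return PanelDefinition(entries)


_PANEL_HEADER = ["name", "class", "carbons", "double_bonds", "modifier",
                 "target_value_uM"]


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel definition as a UTF-8 TSV with empty strings for absent
    numeric fields."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_PANEL_HEADER)
        for e in panel.entries:
            w.writerow([
                e.name,
                e.met_class.value,
                "" if e.carbons is None else e.carbons,
                "" if e.double_bonds is None else e.double_bonds,
                e.modifier.value,
                repr(e.target_value_uM),
            ])


def load_panel(path: str | Path) -> PanelDefinition:
    """Load a panel TSV, re-parsing each name and checking it agrees with the
    stored class/composition columns."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header != _PANEL_HEADER:
            raise PanelError(f"{path}: unexpected panel header {header!r}")
        for row in r:
            if not row:
                continue
            name, cls, x, y, mod, tv = row
            parsed = parse_metabolite_name(name)
            stored = ParsedName(
                MetClass(cls),
                int(x) if x != "" else None,
                int(y) if y != "" else None,
                Modifier(mod),
            )
            if stored != parsed:
                raise PanelError(f"{path}: stored fields for {name!r} disagree "
                                 f"with its parsed name")
            entries.append(
                PanelEntry(name, parsed.met_class, parsed.carbons,
                           parsed.double_bonds, parsed.modifier, float(tv))
            )
    return PanelDefinition(entries)
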
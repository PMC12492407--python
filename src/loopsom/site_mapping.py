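"""In-silico proteolysis and arginine-modification mass bookkeeping.

Models the LC-MS side of a phenylglyoxal (PG) modification experiment at
the level of neutral monoisotopic masses: tryptic digestion with missed
cleavages, fixed carbamidomethylation of cysteine, variable methionine
oxidation and PG-arginine adducts, ppm-window matching of observed neutral
masses to the theoretical ion library, and per-arginine intensity profiles.
Charge-state deconvolution, MS2 scoring and FDR control are out of scope.

Modification deltas are computed from elemental compositions at full
monoisotopic precision; their nominal (integer) values are the familiar
search-engine shifts +57 (carbamidomethyl-C), +16 (oxidation-M) and
+116 (PG-R, i.e. phenylglyoxal C8H6O2 condensed with loss of water).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

from .errors import UndefinedStatisticError, ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    identifier: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError("sequence must be nonempty")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValidationError(f"non-standard residues in sequence: {sorted(bad)}")

    def arginine_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "R"]


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide located on its parent sequence (1-based, inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValidationError("peptide span does not match sequence length")
        if self.missed_cleavages < 0:
            raise ValidationError("missed_cleavages must be >= 0")

    def covers(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


@dataclass(frozen=True)
class ModSpec:
    """A residue-targeted modification with a monoisotopic mass delta (Da)."""

    target: str
    delta: float
    mode: str
    label: str

    def __post_init__(self):
        if self.mode not in ("fixed", "variable"):
            raise ValidationError("mode must be 'fixed' or 'variable'")
        if not np.isfinite(self.delta):
            raise ValidationError("delta must be finite")

    @property
    def nominal(self) -> int:
        return int(round(self.delta))


def _formula_mass(formula: str) -> float:
    return pmass.calculate_mass(formula=formula)


#: Carbamidomethylation of cysteine (iodoacetamide/chloroacetamide alkylation).
CARBAMIDOMETHYL = ModSpec("C", _formula_mass("C2H3NO"), "fixed", "carbamidomethyl")
#: Oxidation of methionine.
OXIDATION = ModSpec("M", _formula_mass("O"), "variable", "oxidation")
#: Phenylglyoxal adduct on arginine: C8H6O2 condensation with water loss.
PHENYLGLYOXAL = ModSpec("R", _formula_mass("C8H4O"), "variable", "phenylglyoxal")

WATER_MONO = _formula_mass("H2O")

#: Trypsin specificity: cleave C-terminal to K or R, suppressed before proline.
TRYPSIN_RULE = re.compile(r"[KR](?=[^P])")
TRYPSIN_RULE_NO_PROLINE_SUPPRESSION = re.compile(r"[KR](?=.)")


@dataclass(frozen=True)
class PeptideIon:
    """A peptide with an applied modification set and its neutral monoisotopic mass."""

    peptide: Peptide
    modifications: tuple[tuple[int, ModSpec], ...]
    mass: float

    def mod_positions(self, label: str | None = None) -> list[int]:
        return [pos for pos, spec in self.modifications
                if label is None or spec.label == label]


def digest(protein: ProteinRecord, max_missed: int = 2,
           proline_suppression: bool = True) -> list[Peptide]:
    """Tryptic digestion: cleave after K/R (not before P), 0..max_missed missed sites.

    Peptides are returned ordered by start position, then length.  Lys-C/
    trypsin double digestion collapses onto this rule for the K/R specificity
    modelled here.
    """
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    seq = protein.sequence
    rule = TRYPSIN_RULE if proline_suppression else TRYPSIN_RULE_NO_PROLINE_SUPPRESSION
    cut_points = [m.end() for m in rule.finditer(seq)]
    boundaries = [0] + cut_points + [len(seq)]
    if boundaries[-1] == boundaries[-2]:
        boundaries.pop()
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for m in range(0, max_missed + 1):
            if i + m + 1 > n_frag:
                break
            start = boundaries[i]
            end = boundaries[i + m + 1]
            peptides.append(
                Peptide(protein.identifier, start + 1, end, seq[start:end], m)
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(peptide: Peptide, mods: Mapping[int, ModSpec] | None = None) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas.

    ``mods`` maps 1-based parent residue positions to modification specs;
    each position must fall inside the peptide and carry the spec's target
    residue.
    """
    base = pmass.fast_mass(peptide.sequence)
    total = base
    for pos, spec in (mods or {}).items():
        if not peptide.covers(pos):
            raise ValidationError(
                f"modification position {pos} outside peptide {peptide.start}-{peptide.end}"
            )
        residue = peptide.sequence[pos - peptide.start]
        if residue != spec.target:
            raise ValidationError(
                f"{spec.label} targets {spec.target}, but position {pos} is {residue!r}"
            )
        total += spec.delta
    return total


def apply_fixed(peptide: Peptide, fixed: Iterable[ModSpec]) -> dict[int, ModSpec]:
    """Placement map of fixed modifications on every eligible residue."""
    placed: dict[int, ModSpec] = {}
    for spec in fixed:
        for offset, aa in enumerate(peptide.sequence):
            if aa == spec.target:
                placed[peptide.start + offset] = spec
    return placed


def enumerate_modified_ions(peptide: Peptide,
                            fixed: Sequence[ModSpec] = (CARBAMIDOMETHYL,),
                            variable: Sequence[ModSpec] = (OXIDATION, PHENYLGLYOXAL),
                            max_variable: int = 3) -> list[PeptideIon]:
    """All modification states of a peptide as neutral ions.

    Fixed mods go on every eligible residue; variable mods are placed on all
    subsets of eligible positions of size 0..max_variable (at most one mod
    per residue).  The unmodified-variable state is always included.
    """
    fixed_placed = apply_fixed(peptide, fixed)
    slots: list[tuple[int, ModSpec]] = []
    for spec in variable:
        for offset, aa in enumerate(peptide.sequence):
            pos = peptide.start + offset
            if aa == spec.target and pos not in fixed_placed:
                slots.append((pos, spec))
    ions = []
    seen = set()
    for size in range(0, min(max_variable, len(slots)) + 1):
        for combo in combinations(slots, size):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            placement = dict(fixed_placed)
            placement.update(dict(combo))
            key = tuple(sorted((p, s.label) for p, s in placement.items()))
            if key in seen:
                continue
            seen.add(key)
            ions.append(
                PeptideIon(
                    peptide,
                    tuple(sorted(placement.items())),
                    peptide_mass(peptide, placement),
                )
            )
    return ions


def build_ion_library(protein: ProteinRecord, max_missed: int = 2,
                      fixed: Sequence[ModSpec] = (CARBAMIDOMETHYL,),
                      variable: Sequence[ModSpec] = (OXIDATION, PHENYLGLYOXAL),
                      max_variable: int = 3) -> list[PeptideIon]:
    """Theoretical neutral-ion library for a whole protein digest."""
    ions = []
    for pep in digest(protein, max_missed=max_missed):
        ions.extend(enumerate_modified_ions(pep, fixed, variable, max_variable))
    return ions


def match_masses(theoretical: Sequence[PeptideIon], observed: pd.DataFrame,
                 tol_ppm: float = 20.0) -> pd.DataFrame:
    """Match observed neutral masses to theoretical ions within a ppm window.

    ``observed`` needs columns ``mass_da`` and ``intensity``.  Every match
    within tolerance is reported (no uniqueness is forced); observations
    matching more than one ion are flagged ``ambiguous``.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    theo_masses = np.array([ion.mass for ion in theoretical])
    rows = []
    for obs_idx, row in observed.reset_index(drop=True).iterrows():
        m = float(row["mass_da"])
        ppm_all = (m - theo_masses) / theo_masses * 1e6
        hit_idx = np.nonzero(np.abs(ppm_all) <= tol_ppm)[0]
        hits = [(theoretical[j], float(ppm_all[j])) for j in hit_idx]
        for ion, ppm in hits:
            rows.append(
                {
                    "observation": int(obs_idx),
                    "mass_da": m,
                    "intensity": float(row["intensity"]),
                    "peptide": ion.peptide.sequence,
                    "start": ion.peptide.start,
                    "end": ion.peptide.end,
                    "ppm_error": ppm,
                    "pg_positions": tuple(ion.mod_positions("phenylglyoxal")),
                    "ambiguous": len(hits) > 1,
                    "ion": ion,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["observation", "mass_da", "intensity", "peptide", "start", "end",
                 "ppm_error", "pg_positions", "ambiguous", "ion"],
    )


def site_profile(matches: pd.DataFrame, protein: ProteinRecord,
                 normalize: str = "max", include_ambiguous: bool = False,
                 ) -> pd.DataFrame:
    """Per-arginine summed intensity of matched PG-bearing ions.

    Emulates a modification-site intensity plot: x = residue number of each
    arginine in the protein, y = summed intensity of matched observations
    whose PG placement is that residue.  ``normalize`` is ``"max"`` (relative
    to the most intense site), ``"sum"`` or ``"none"``.

    By default only unambiguously matched observations contribute: a neutral
    mass cannot localize a modification among several equal-mass placements
    (that takes fragment spectra, which are out of scope), so counting
    ambiguous matches would smear intensity onto unmodified arginines.
    """
    if normalize not in ("max", "sum", "none"):
        raise ValidationError("normalize must be 'max', 'sum' or 'none'")
    totals = {pos: 0.0 for pos in protein.arginine_positions()}
    for _, row in matches.iterrows():
        if not include_ambiguous and bool(row.get("ambiguous", False)):
            continue
        for pos in row["pg_positions"]:
            if pos in totals:
                totals[pos] += row["intensity"]
    df = pd.DataFrame(
        {"residue_index": list(totals), "intensity": list(totals.values())}
    ).sort_values("residue_index", ignore_index=True)
    denom = 1.0
    if normalize == "max" and df["intensity"].max() > 0:
        denom = df["intensity"].max()
    elif normalize == "sum" and df["intensity"].sum() > 0:
        denom = df["intensity"].sum()
    df["relative_intensity"] = df["intensity"] / denom
    return df


def percent_modification(od_control: float, od_sample: float) -> float:
    """Percent of reactive amine content lost: (OD_c - OD_s) / OD_c * 100.

    Absorbances are at 420 nm from a TNBSA primary-amine assay.  Negative
    values (sample above control) are allowed and simply reported.
    """
    if od_control <= 0:
        raise ValidationError("od_control must be positive")
    return (od_control - od_sample) / od_control * 100.0


def sample_std(values) -> float:
    """Sample standard deviation with the N-1 denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise UndefinedStatisticError("sample SD needs at least 2 observations")
    return float(np.sqrt(np.sum((x - x.mean()) ** 2) / (x.size - 1)))


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA into ProteinRecords."""
    from Bio import SeqIO

    return [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_ion_table(ions: Sequence[PeptideIon], path) -> None:
    """Write an ion library as TSV (accession, start, end, sequence, missed, mods, mass_da)."""
    rows = [
        {
            "accession": ion.peptide.parent_id,
            "start": ion.peptide.start,
            "end": ion.peptide.end,
            "sequence": ion.peptide.sequence,
            "missed": ion.peptide.missed_cleavages,
            "mods": ";".join(f"{spec.label}@{pos}" for pos, spec in ion.modifications),
            "mass_da": ion.mass,
        }
        for ion in ions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
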
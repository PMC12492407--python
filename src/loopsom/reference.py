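"""Reference data for the cashew 2S albumin allergen Ana o 3.

Ana o 3.0101 (UniProt Q8H2B8) is synthesized as a 138-residue precursor;
the mature 2S albumin chain spans precursor residues 24-138 and carries
15 arginines and 8 cysteines forming four conserved disulfide bonds.
Structural work on this allergen uses precursor numbering (e.g. the
flexible "non-native" loop E59-N67), so helpers here convert between
mature-chain positions (1-based on the sequence below) and precursor
residue numbers (offset +23).

The homology model underlying the dynamics analysis covers precursor
residues S38-Q135 with disulfides C39-C87, C52-C76, C77-C124 and
C89-C132.
"""

from __future__ import annotations

from .errors import ValidationError
from .geometry import ResidueRange
from .site_mapping import ProteinRecord

#: Mature Ana o 3.0101 chain (UniProt Q8H2B8, precursor residues 24-138).
ANA_O_3_MATURE_SEQUENCE = (
    "TTMVEVEEDSGREQS"          # 24-38
    "CQRQFEEQQRFRNCQR"         # 39-54
    "YVKQEVQRGGRYNQRQESLRECC"  # 55-77
    "QELQEVDRRCRCQNLEQMV"      # 78-96
    "RQLQQQEQIKGEEVRELYETASELPR"  # 97-122
    "ICSISPSQGCQFQSSY"         # 123-138
)

ANA_O_3_MATURE = ProteinRecord("Q8H2B8|ANA_O_3.0101|mature", ANA_O_3_MATURE_SEQUENCE)

#: Offset between mature-chain position and precursor residue number.
PRECURSOR_OFFSET = 23

#: Disulfide pairings of the modelled structure, precursor numbering.
DISULFIDE_PAIRS = ((39, 87), (52, 76), (77, 124), (89, 132))

#: Arginines observed with the highest phenylglyoxal-adduct intensities.
PG_MODIFIED_SITES = (41, 54, 85, 111)

#: Immunogen peptide used to raise the 2H5 monoclonal antibody
#: (precursor residues 39-54).
IMMUNOGEN_2H5 = "CQRQFEEQQRFRNCQR"

#: Residue ranges of the dynamics analysis, precursor numbering.
MODEL_RANGE = ResidueRange(38, 135, "modelled chain S38-Q135")
DIHEDRAL_RANGES = (
    ResidueRange(61, 77, "Q61-C77"),
    ResidueRange(106, 112, "K106-E112"),
)
NON_NATIVE_LOOP = ResidueRange(59, 67, "non-native loop E59-N67")
HYPERVARIABLE_LOOP = ResidueRange(103, 107, "hypervariable loop E103-G107")
RMSD_LOOP_SUBSET = ResidueRange(59, 71, "E59-E71 Calpha")

#: Simulated system labels: unmodified control, four single-site PG
#: modifications and the saturating quadruple modification.
SYSTEMS = ("WT", "R41PG", "R54PG", "R85PG", "R111PG", "quadruple-PG")

#: Dihedral angles retained by the divergence filter in the original
#: microsecond-trajectory analysis; shipped only as a label-format fixture
#: (the selection is trajectory-dependent and not reproducible at desk scale).
EDA_SELECTED_ANGLES = (
    "Q61_psi", "G63_phi", "R65_phi", "R65_psi", "Q68_phi", "R69_phi",
    "Q70_psi", "E71_psi", "S72_psi", "L73_psi", "G107_phi", "G107_psi",
    "E108_phi", "E109_phi", "E109_psi", "V110_phi", "V110_psi",
    "R111_phi", "R111_psi", "E112_phi", "E112_psi",
)


def precursor_to_mature(residue: int) -> int:
    """Precursor residue number -> 1-based mature-chain position."""
    pos = residue - PRECURSOR_OFFSET
    if not 1 <= pos <= len(ANA_O_3_MATURE_SEQUENCE):
        raise ValidationError(f"precursor residue {residue} outside the mature chain")
    return pos


def mature_to_precursor(position: int) -> int:
    """1-based mature-chain position -> precursor residue number."""
    if not 1 <= position <= len(ANA_O_3_MATURE_SEQUENCE):
        raise ValidationError(f"mature position {position} out of range")
    return position + PRECURSOR_OFFSET


def disulfide_graph(pairs=DISULFIDE_PAIRS, sequence: str = ANA_O_3_MATURE_SEQUENCE,
                    offset: int = PRECURSOR_OFFSET):
    """Build the disulfide-bond graph, validating both partners are cysteines.

    Nodes are precursor residue numbers; each stated pairing contributes one
    edge.  Returns a ``networkx.Graph``.
    """
    import networkx as nx

    g = nx.Graph()
    for a, b in pairs:
        for res in (a, b):
            aa = sequence[res - offset - 1]
            if aa != "C":
                raise ValidationError(
                    f"disulfide partner {res} is {aa!r}, not cysteine"
                )
        if a == b:
            raise ValidationError("a disulfide cannot link a cysteine to itself")
        g.add_edge(a, b)
    return g


def count_disulfide_bonds() -> int:
    """Number of disulfide bonds in the modelled structure."""
    return disulfide_graph().number_of_edges()


def count_mature_arginines() -> int:
    """Arginine census of the mature Ana o 3.0101 chain."""
    return len(ANA_O_3_MATURE.arginine_positions())
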
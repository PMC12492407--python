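"""Tryptic digestion, modification mass bookkeeping, ppm matching,
site-intensity profiles and the assay arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopsom.errors import UndefinedStatisticError, ValidationError
from loopsom.reference import (ANA_O_3_MATURE, IMMUNOGEN_2H5,
                               PG_MODIFIED_SITES, precursor_to_mature)
from loopsom.site_mapping import (CARBAMIDOMETHYL, OXIDATION, PHENYLGLYOXAL,
                                  Peptide, ProteinRecord, build_ion_library,
                                  digest, enumerate_modified_ions,
                                  match_masses, peptide_mass,
                                  percent_modification, sample_std,
                                  site_profile)
from loopsom.synthetic import simulate_peptide_observations


def oracle_digest(sequence: str, max_missed: int) -> set[tuple[int, str]]:
    """Independent enumeration: fragments from a character scan, then all
    runs of <= max_missed + 1 consecutive fragments."""
    frags = []
    current = ""
    for i, aa in enumerate(sequence):
        current += aa
        nxt = sequence[i + 1] if i + 1 < len(sequence) else ""
        if aa in "KR" and nxt and nxt != "P":
            frags.append(current)
            current = ""
    if current:
        frags.append(current)
    out = set()
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed + 1, len(frags))):
            seq = "".join(frags[i:j + 1])
            start = sum(len(f) for f in frags[:i]) + 1
            out.add((start, seq))
    return out


class TestDigest:
    immunogen = ProteinRecord("2H5", IMMUNOGEN_2H5)

    def test_immunogen_zero_missed(self):
        peptides = [p.sequence for p in digest(self.immunogen, 0)]
        assert peptides == ["CQR", "QFEEQQR", "FR", "NCQR"]

    def test_immunogen_two_missed_counts(self):
        peptides = digest(self.immunogen, 2)
        assert len(peptides) == 9
        by_missed = {m: sum(p.missed_cleavages == m for p in peptides)
                     for m in (0, 1, 2)}
        assert by_missed == {0: 4, 1: 3, 2: 2}

    def test_matches_enumeration_oracle(self):
        got = {(p.start, p.sequence) for p in digest(self.immunogen, 2)}
        assert got == oracle_digest(IMMUNOGEN_2H5, 2)

    def test_proline_suppression(self):
        assert [p.sequence for p in digest(ProteinRecord("x", "AKPA"), 0)] == ["AKPA"]
        no_rule = digest(ProteinRecord("x", "AKPA"), 0, proline_suppression=False)
        assert [p.sequence for p in no_rule] == ["AK", "PA"]

    def test_cterminal_kr_not_an_extra_site(self):
        assert [p.sequence for p in digest(ProteinRecord("x", "AAKR"), 0)] == [
            "AAK", "R"
        ]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEGKLPRS", min_size=1, max_size=40))
    def test_digest_properties(self, sequence):
        protein = ProteinRecord("h", sequence)
        zero = digest(protein, 0)
        # concatenation of zero-missed peptides reconstructs the sequence
        assert "".join(p.sequence for p in zero) == sequence
        f = len(zero)
        full = digest(protein, max_missed=f)
        for m in range(f):
            assert sum(p.missed_cleavages == m for p in full) == f - m
        assert {(p.start, p.sequence) for p in digest(protein, 2)} == (
            oracle_digest(sequence, 2)
        )


class TestMasses:
    def test_glycine_neutral_mass(self):
        g = Peptide("x", 1, 1, "G", 0)
        assert peptide_mass(g) == pytest.approx(75.03203, abs=1e-5)

    def test_modification_deltas_full_precision(self):
        assert PHENYLGLYOXAL.delta == pytest.approx(116.02621, abs=1e-5)
        assert CARBAMIDOMETHYL.delta == pytest.approx(57.02146, abs=1e-5)
        assert OXIDATION.delta == pytest.approx(15.99491, abs=1e-5)

    def test_mass_additivity_exact(self):
        pep = Peptide("x", 1, 4, "CMRK", 0)
        mods = {1: CARBAMIDOMETHYL, 2: OXIDATION, 3: PHENYLGLYOXAL}
        delta = peptide_mass(pep, mods) - peptide_mass(pep)
        assert delta == pytest.approx(
            CARBAMIDOMETHYL.delta + OXIDATION.delta + PHENYLGLYOXAL.delta,
            abs=1e-9,
        )

    def test_mod_on_wrong_residue_rejected(self):
        pep = Peptide("x", 1, 2, "AG", 0)
        with pytest.raises(ValidationError):
            peptide_mass(pep, {1: PHENYLGLYOXAL})


class TestEnumerateIons:
    def test_cqr_fixed_cam_variable_pg(self):
        pep = Peptide("x", 1, 3, "CQR", 0)
        ions = enumerate_modified_ions(pep, (CARBAMIDOMETHYL,),
                                       (PHENYLGLYOXAL,), 2)
        assert len(ions) == 2
        deltas = sorted(ion.mass - peptide_mass(pep) for ion in ions)
        assert deltas[0] == pytest.approx(CARBAMIDOMETHYL.delta, abs=1e-9)
        assert deltas[1] == pytest.approx(
            CARBAMIDOMETHYL.delta + PHENYLGLYOXAL.delta, abs=1e-9
        )

    def test_unmodifiable_peptide_single_ion(self):
        pep = Peptide("x", 1, 3, "AGL", 0)
        assert len(enumerate_modified_ions(pep)) == 1

    def test_two_arginines_four_states(self):
        pep = Peptide("x", 1, 2, "RR", 0)
        ions = enumerate_modified_ions(pep, (), (PHENYLGLYOXAL,), 2)
        assert len(ions) == 4

    def test_max_variable_caps_enumeration(self):
        pep = Peptide("x", 1, 4, "RRRR", 0)
        ions = enumerate_modified_ions(pep, (), (PHENYLGLYOXAL,), 1)
        assert len(ions) == 5  # none + 4 singles


class TestMatching:
    def test_exact_match_zero_ppm(self):
        protein = ProteinRecord("t", "CQRQFEEQQR")
        ions = build_ion_library(protein)
        observed = pd.DataFrame(
            {"mass_da": [ions[0].mass], "intensity": [1.0]}
        )
        matches = match_masses(ions, observed)
        ours = matches[matches["observation"] == 0]
        assert (ours["ppm_error"].abs() < 1e-9).any()

    def test_offset_beyond_tolerance_excluded(self):
        protein = ProteinRecord("t", "AAAGGGK")
        ions = build_ion_library(protein)
        observed = pd.DataFrame(
            {"mass_da": [ions[0].mass * (1 + 25e-6)], "intensity": [1.0]}
        )
        assert match_masses(ions, observed, tol_ppm=20.0).empty

    def test_noisy_observations_mostly_recovered(self):
        protein = ProteinRecord("t", ANA_O_3_MATURE.sequence[:60])
        ions = build_ion_library(protein)
        matched = 0
        total = 0
        for seed in range(10):
            obs = simulate_peptide_observations(
                protein, [], [], ppm_noise=5.0, seed=seed
            )
            total += len(obs)
            matches = match_masses(ions, obs, tol_ppm=20.0)
            matched += matches["observation"].nunique()
        assert total >= 100
        assert matched / total >= 0.99


class TestSiteProfile:
    def test_planted_sites_recovered_with_hand_counted_intensities(self):
        protein = ProteinRecord("t", "AAARGGGKCCCRDDDK")
        obs = simulate_peptide_observations(
            protein, [4, 12], [100.0, 50.0], ppm_noise=0.0
        )
        ions = build_ion_library(protein)
        matches = match_masses(ions, obs)
        pg = matches[matches["pg_positions"].map(len) > 0]
        profile = site_profile(pg, protein, normalize="none")
        by_site = profile.set_index("residue_index")["intensity"]
        # unambiguous peptides covering R4: AAAR, AAARGGGK -> 2 x 100;
        # covering R12: CCCR, GGGKCCCR, CCCRDDDK, GGGKCCCRDDDK -> 4 x 50
        assert by_site[4] == pytest.approx(200.0)
        assert by_site[12] == pytest.approx(200.0)

    def test_no_pg_matches_all_zero(self):
        protein = ProteinRecord("t", "AAARGGGK")
        profile = site_profile(pd.DataFrame(columns=["pg_positions", "intensity"]),
                               protein)
        assert (profile["intensity"] == 0).all()

    def test_overlapping_peptides_sum(self):
        protein = ProteinRecord("t", "KARAK")
        matches = pd.DataFrame(
            {
                "pg_positions": [(3,), (3,)],
                "intensity": [10.0, 7.0],
            }
        )
        profile = site_profile(matches, protein, normalize="none")
        assert profile.set_index("residue_index")["intensity"][3] == 17.0


class TestAssayArithmetic:
    @pytest.mark.parametrize(
        "control, sample, expected",
        [(1.0, 0.5, 50.0), (0.8, 0.8, 0.0), (0.5, 0.6, -20.0)],
    )
    def test_percent_modification(self, control, sample, expected):
        assert percent_modification(control, sample) == pytest.approx(expected)

    def test_percent_modification_requires_positive_control(self):
        with pytest.raises(ValidationError):
            percent_modification(0.0, 0.1)

    def test_sample_std_reference_values(self):
        assert sample_std([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert sample_std([4.0, 4.0, 4.0]) == 0.0

    def test_sample_std_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        direct = np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1))
        assert sample_std(x) == pytest.approx(direct, abs=1e-12)

    def test_sample_std_needs_two_values(self):
        with pytest.raises(UndefinedStatisticError):
            sample_std([1.0])


def test_planted_site_roundtrip_on_allergen_sequence():
    """Planted PG sites on the mature allergen chain are recovered exactly
    at zero mass noise, and only those sites carry signal."""
    sites = [precursor_to_mature(r) for r in PG_MODIFIED_SITES]
    obs = simulate_peptide_observations(
        ANA_O_3_MATURE, sites, [1000.0] * len(sites), ppm_noise=0.0
    )
    ions = build_ion_library(ANA_O_3_MATURE)
    matches = match_masses(ions, obs)
    pg = matches[matches["pg_positions"].map(len) > 0]
    profile = site_profile(pg, ANA_O_3_MATURE, normalize="none")
    detected = set(profile[profile["intensity"] > 0]["residue_index"])
    assert detected == set(sites)
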
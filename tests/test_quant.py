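"""DIA windows, XIC quantification, rollup, normalization, fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodia.library import IonLibrary, TransitionRecord
from glycodia.quant import (
    AbundanceMatrix,
    glycoform_fractions,
    make_windows,
    normalize_to_reference,
    normalize_total,
    quantify_transitions,
    rollup,
)
from glycodia import simulate


class TestWindows:
    @pytest.mark.parametrize(
        "args,count",
        [((400, 1250, 26, 1), 34), ((400, 426, 26, 1), 1), ((0, 100, 26, 1), 4)],
    )
    def test_window_counts(self, args, count):
        assert len(make_windows(*args)) == count

    def test_window_starts(self):
        scheme = make_windows(0, 100, 26, 1)
        assert [w[0] for w in scheme.windows] == [0, 25, 50, 75]
        assert all(w[1] - w[0] == 26 for w in scheme.windows)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_windows(400, 1250, 1, 26)
        with pytest.raises(ValueError):
            make_windows(500, 400, 26, 1)

    @given(
        low=st.floats(0, 500),
        span=st.floats(30, 2000),
        width=st.floats(5, 50),
        overlap=st.floats(0, 4),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_coverage_and_overlap_properties(self, low, span, width, overlap):
        scheme = make_windows(low, low + span, width, overlap)
        starts = np.array([w[0] for w in scheme.windows])
        ends = np.array([w[1] for w in scheme.windows])
        assert np.allclose(ends - starts, width)
        # consecutive windows overlap by exactly `overlap`
        if len(scheme) > 1:
            assert np.allclose(ends[:-1] - starts[1:], overlap)
        # full coverage of [low, high] (fp slack)
        assert starts[0] <= low + 1e-7
        assert ends[-1] >= low + span - 1e-7
        # terminal overhang below one extra window
        assert ends[-1] - (low + span) < width + 1e-7

    def test_assignment_unique(self):
        scheme = make_windows(400, 1250, 26, 1)
        assert scheme.assign(746.33) is not None
        assert scheme.assign(300.0) is None
        for mz in (400.5, 425.5, 1249.0):
            i = scheme.assign(mz)
            assert scheme.windows[i][0] <= mz <= scheme.windows[i][1]


def transition(seq, slot, q3, rt=10.0, z=2, frg_z=1, li=100.0, protein="P1"):
    return TransitionRecord(
        q1=500.0,
        q3=q3,
        rt=rt,
        protein=protein,
        slot=slot,
        relative_intensity=li,
        stripped_sequence=seq.split("[")[0],
        modified_sequence=seq,
        precursor_charge=z,
        fragment_charge=frg_z,
    )


class TestQuantifyTransitions:
    def lib(self):
        return IonLibrary([transition("PEP[Hex1]", "b2", 300.0)])

    def peaks(self, mz, rt, intensity):
        return pd.DataFrame({"mz": [mz], "rt_min": [rt], "intensity": [intensity]})

    def test_planted_peak_recovered(self):
        m = quantify_transitions(self.lib(), {"s1": self.peaks(300.0, 10.0, 1000.0)})
        assert m.data.loc["PEP[Hex1]/2/b2/1", "s1"] == 1000.0

    def test_peak_outside_ppm_width_ignored(self):
        off = 300.0 * (1 + 100e-6)  # 100 ppm away
        m = quantify_transitions(
            self.lib(), {"s1": self.peaks(off, 10.0, 1000.0)}, xic_ppm=75.0
        )
        assert m.data.loc["PEP[Hex1]/2/b2/1", "s1"] == 0.0

    def test_peak_outside_rt_window_ignored(self):
        m = quantify_transitions(
            self.lib(), {"s1": self.peaks(300.0, 14.0, 1000.0)}, rt_window=6.0
        )
        assert m.data.loc["PEP[Hex1]/2/b2/1", "s1"] == 0.0

    def test_missing_sample_errors(self):
        with pytest.raises(ValueError, match="s1"):
            quantify_transitions(self.lib(), {"s1": None})

    def test_synthetic_recovery_within_one_percent(self):
        cfg = simulate.default_config(seed=7, cv=0.0)
        report, _ = simulate.simulate_identifications(cfg)
        from glycodia.library import build_library, read_id_report
        import io

        buf = io.StringIO()
        report.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        lib = build_library(read_id_report(buf).psms)
        dia = simulate.simulate_dia(cfg, lib)
        m = quantify_transitions(lib, dia.samples)
        truth = dia.truth_transitions
        for cond, names in dia.design.items():
            t = truth[truth["condition"] == cond]
            for row in t.itertuples():
                tid = f"{row.modified_sequence}/{row.prec_z}/{row.slot}/{row.frg_z}"
                for s in names:
                    got = m.data.loc[tid, s]
                    assert got == pytest.approx(row.intensity, rel=0.01)


class TestRollup:
    def build(self, records, data):
        lib = IonLibrary(records)
        samples = {
            col: pd.DataFrame(
                {
                    "modified_sequence": [r.modified_sequence for r in records],
                    "prec_z": [r.precursor_charge for r in records],
                    "slot": [r.slot for r in records],
                    "frg_z": [r.fragment_charge for r in records],
                    "intensity": vals,
                }
            )
            for col, vals in data.items()
        }
        return quantify_transitions(lib, samples)

    def test_sum_below_k(self):
        records = [
            transition("PEP", "b2", 300.0, li=10.0),
            transition("PEP", "y3", 400.0, li=20.0),
        ]
        m = self.build(records, {"s1": [10.0, 20.0]})
        peptides, _ = rollup(m, k=6)
        assert peptides.data.loc["PEP/2", "s1"] == 30.0

    def test_top_k_limits(self):
        records = [
            transition("PEP", f"y{i}", 300.0 + i, li=1.0) for i in range(2, 10)
        ]
        m = self.build(records, {"s1": [1.0] * 8})
        peptides, _ = rollup(m, k=6)
        assert peptides.data.loc["PEP/2", "s1"] == 6.0

    def test_shared_peptide_counts_for_every_parent(self):
        records = [transition("PEP", "b2", 300.0, protein="P1;P2", li=5.0)]
        m = self.build(records, {"s1": [8.0]})
        _, proteins = rollup(m)
        assert proteins.data.loc["P1", "s1"] == 8.0
        assert proteins.data.loc["P2", "s1"] == 8.0


class TestNormalization:
    def matrix(self, rows):
        return AbundanceMatrix(
            data=pd.DataFrame(rows, columns=["s1", "s2"]), level="protein"
        )

    def test_reference_division(self):
        m = self.matrix({"trypsin": [2.0, 4.0], "P1": [4.0, 4.0]}.values())
        m.data.index = ["trypsin", "P1"]
        out = normalize_to_reference(m, "trypsin")
        assert out.data.loc["P1"].tolist() == [2.0, 1.0]
        assert out.data.loc["trypsin"].tolist() == [1.0, 1.0]

    def test_zero_reference_names_sample(self):
        m = self.matrix({"trypsin": [2.0, 0.0], "P1": [4.0, 4.0]}.values())
        m.data.index = ["trypsin", "P1"]
        with pytest.raises(ValueError, match="s2"):
            normalize_to_reference(m, "trypsin")

    def test_absent_reference(self):
        m = self.matrix({"P1": [4.0, 4.0]}.values())
        m.data.index = ["P1"]
        with pytest.raises(ValueError, match="trypsin"):
            normalize_to_reference(m, "trypsin")

    def test_scale_invariance(self, rng):
        data = pd.DataFrame(
            rng.uniform(1, 100, size=(10, 3)),
            index=[f"P{i}" for i in range(9)] + ["ref"],
            columns=["a", "b", "c"],
        )
        m = AbundanceMatrix(data=data, level="protein")
        scaled = AbundanceMatrix(data=data * [3.0, 1.0, 0.5], level="protein")
        out1 = normalize_to_reference(m, "ref").data
        out2 = normalize_to_reference(scaled, "ref").data
        assert np.allclose(out1, out2)
        # and equals brute-force elementwise division
        brute = data / data.loc["ref"]
        assert np.allclose(out1, brute)

    def test_total_normalization_columns_sum_to_one(self, rng):
        data = pd.DataFrame(rng.uniform(1, 100, size=(5, 3)))
        out = normalize_total(AbundanceMatrix(data=data, level="protein"))
        assert np.allclose(out.data.sum(axis=0), 1.0)


def peptide_matrix(entries, samples):
    """entries: list of (modified_sequence, prec_z, stripped, protein, values)."""
    ids = [f"{e[0]}/{e[1]}" for e in entries]
    data = pd.DataFrame(
        [e[4] for e in entries], index=ids, columns=samples, dtype=float
    )
    meta = pd.DataFrame(
        {
            "modified_sequence": [e[0] for e in entries],
            "stripped_sequence": [e[2] for e in entries],
            "prec_z": [e[1] for e in entries],
            "protein": [e[3] for e in entries],
        },
        index=ids,
    )
    return AbundanceMatrix(data=data, level="peptide", meta=meta)


class TestGlycoformFractions:
    def test_two_forms(self):
        m = peptide_matrix(
            [
                ("PEP[Hex2]", 2, "PEP", "P1", [100.0]),
                ("PEP[Hex3]", 2, "PEP", "P1", [300.0]),
            ],
            ["s1"],
        )
        prof = glycoform_fractions(m)
        assert prof.fractions.loc[("PEP", "Hex2"), "s1"] == 0.25
        assert prof.fractions.loc[("PEP", "Hex3"), "s1"] == 0.75

    def test_single_form_is_one(self):
        m = peptide_matrix([("PEP[Hex2]", 2, "PEP", "P1", [42.0])], ["s1"])
        assert glycoform_fractions(m).fractions.iloc[0, 0] == 1.0

    def test_charge_states_summed_first(self):
        m = peptide_matrix(
            [
                ("PEP[Hex2]", 2, "PEP", "P1", [60.0]),
                ("PEP[Hex2]", 3, "PEP", "P1", [40.0]),
                ("PEP[Hex3]", 2, "PEP", "P1", [100.0]),
            ],
            ["s1"],
        )
        prof = glycoform_fractions(m)
        assert prof.fractions.loc[("PEP", "Hex2"), "s1"] == 0.5
        assert prof.fractions.loc[("PEP", "Hex3"), "s1"] == 0.5

    def test_unmodified_form_included(self):
        m = peptide_matrix(
            [
                ("PEP", 2, "PEP", "P1", [100.0]),
                ("PEP[Hex1]", 2, "PEP", "P1", [100.0]),
            ],
            ["s1"],
        )
        prof = glycoform_fractions(m)
        assert prof.fractions.loc[("PEP", "unmodified"), "s1"] == 0.5

    def test_grouping_pools_cleavage_variants(self):
        m = peptide_matrix(
            [
                ("VITGVPWYSSR[Hex2]", 2, "VITGVPWYSSR", "P1", [50.0]),
                ("VITGVPWYSSL[Hex2]", 2, "VITGVPWYSSL", "P1", [50.0]),
                ("VITGVPWYSSR[Hex3]", 2, "VITGVPWYSSR", "P1", [100.0]),
            ],
            ["s1"],
        )
        grouping = {"VITGVPWYSSR": "fam", "VITGVPWYSSL": "fam"}
        prof = glycoform_fractions(m, grouping)
        assert prof.fractions.loc[("fam", "Hex2"), "s1"] == 0.5
        assert prof.fractions.loc[("fam", "Hex3"), "s1"] == 0.5

    def test_all_zero_family_reports_missing(self):
        m = peptide_matrix(
            [
                ("PEP[Hex2]", 2, "PEP", "P1", [0.0, 10.0]),
                ("PEP[Hex3]", 2, "PEP", "P1", [0.0, 30.0]),
            ],
            ["s1", "s2"],
        )
        prof = glycoform_fractions(m)
        assert prof.fractions["s1"].isna().all()
        assert prof.fractions["s2"].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_family(self, rng):
        entries = []
        for fam in range(5):
            for g in range(4):
                entries.append(
                    (
                        f"PEP{fam}[Hex{g + 1}]",
                        2,
                        f"PEP{fam}",
                        "P1",
                        rng.uniform(1, 100, size=3).tolist(),
                    )
                )
        m = peptide_matrix(entries, ["s1", "s2", "s3"])
        sums = glycoform_fractions(m).fractions.groupby(level="family").sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
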
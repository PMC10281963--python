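"""DockQ components and ranking metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from ifaceqe.evaluation import (RankingTable, capri_class, compute_dockq,
                                compute_fnat, compute_irms, compute_lrms,
                                dockq_for_model, evaluate_dataset, hit_rate,
                                minmax_normalize, native_interface_residues,
                                roc_auc, rms_scaled, score_correlation,
                                success_rate, superpose_kabsch,
                                write_target_tsv)
from ifaceqe.structure_model import ComplexStructure
from ifaceqe.synthetic_data import transform_chain

from conftest import random_rigid


class TestRmsScaledAndDockQ:
    def test_printed_example(self):
        """DockQ of (Fnat, LRMS, iRMS) = (0.5, 8.5, 1.5) is exactly 0.5."""
        r = compute_dockq(0.5, 8.5, 1.5)
        assert r.dockq == pytest.approx(0.5)

    @pytest.mark.parametrize("rms,d,expected", [
        (0.0, 8.5, 1.0), (8.5, 8.5, 0.5), (1.5, 1.5, 0.5), (3.0, 1.5, 0.2),
    ])
    def test_rms_scaled(self, rms, d, expected):
        assert rms_scaled(rms, d) == pytest.approx(expected)

    def test_perfect_model(self):
        assert compute_dockq(1.0, 0.0, 0.0).dockq == pytest.approx(1.0)

    @pytest.mark.parametrize("dockq,cls", [
        (0.81, "high"), (0.80, "high"), (0.79, "medium"), (0.49, "medium"),
        (0.30, "acceptable"), (0.23, "acceptable"), (0.229, "incorrect"),
        (0.0, "incorrect"),
    ])
    def test_capri_classes(self, dockq, cls):
        assert capri_class(dockq) == cls

    def test_monotone_in_components(self, rng):
        for _ in range(50):
            f, l, i = rng.uniform(0, 1), rng.uniform(0, 30), rng.uniform(0, 15)
            base = compute_dockq(f, l, i).dockq
            assert compute_dockq(min(f + 0.1, 1), l, i).dockq > base
            assert compute_dockq(f, l + 1, i).dockq < base
            assert compute_dockq(f, l, i + 1).dockq < base


class TestSuperposition:
    def test_recovers_random_rigid_transform(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(12, 3)) * 5
            R, t = random_rigid(rng)
            Rhat, that, rmsd = superpose_kabsch(pts, pts @ R.T + t)
            assert rmsd == pytest.approx(0.0, abs=1e-6)
            assert np.allclose(Rhat, R, atol=1e-6)
            assert np.allclose(that, t, atol=1e-5)
            assert np.linalg.det(Rhat) == pytest.approx(1.0)

    def test_rmsd_matches_direct_formula(self, rng):
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=(10, 3))
        R, t, rmsd = superpose_kabsch(a, b)
        direct = np.sqrt((((a @ R.T + t) - b) ** 2).sum(axis=1).mean())
        assert rmsd == pytest.approx(direct, abs=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDockQOnStructures:
    def test_native_against_itself_is_perfect(self, native):
        r = dockq_for_model(native, native)
        assert r.fnat == pytest.approx(1.0)
        assert r.lrms == pytest.approx(0.0, abs=1e-9)
        assert r.irms == pytest.approx(0.0, abs=1e-9)
        assert r.dockq == pytest.approx(1.0)
        assert r.capri_class == "high"

    def test_rigidly_moved_complex_is_still_perfect(self, native, rng):
        """DockQ is invariant when the whole complex moves rigidly."""
        R, t = random_rigid(rng)
        moved = ComplexStructure(chains=(
            transform_chain(native.chains[0], R, t),
            transform_chain(native.chains[1], R, t)))
        r = dockq_for_model(moved, native)
        assert r.dockq == pytest.approx(1.0, abs=1e-9)

    def test_translated_ligand_lrms_equals_translation(self, native):
        """Pure ligand translation: LRMS is exactly the shift magnitude."""
        for shift in (2.0, 5.0, 12.0):
            decoy = ComplexStructure(chains=(
                native.chains[0],
                transform_chain(native.chains[1], np.eye(3),
                                np.array([0.0, 0.0, shift]))))
            assert compute_lrms(decoy, native) == pytest.approx(shift,
                                                                abs=1e-9)

    def test_far_ligand_fnat_zero(self, native):
        decoy = ComplexStructure(chains=(
            native.chains[0],
            transform_chain(native.chains[1], np.eye(3),
                            np.array([500.0, 0, 0]))))
        assert compute_fnat(decoy, native) == 0.0

    def test_fnat_matches_brute_force(self, native, decoy_set):
        for _, decoy, _ in decoy_set.decoys[:5]:
            # independent recount of preserved native contacts at 5 A
            def contacts(c):
                out = set()
                for i, r1 in enumerate(c.chains[0]):
                    for j, r2 in enumerate(c.chains[1]):
                        d = min(np.linalg.norm(a - b)
                                for a in r1.heavy_atom_coords()
                                for b in r2.heavy_atom_coords())
                        if d < 5.0:
                            out.add((i, j))
                return out
            nat, mod = contacts(native), contacts(decoy)
            assert compute_fnat(decoy, native) == pytest.approx(
                len(nat & mod) / len(nat))

    def test_native_interface_residues_brute_force(self, native):
        if1, if2 = native_interface_residues(native)
        from ifaceqe.structure_model import interaction_coordinate
        expect1, expect2 = set(), set()
        for i, r1 in enumerate(native.chains[0]):
            for j, r2 in enumerate(native.chains[1]):
                d = np.linalg.norm(interaction_coordinate(r1)
                                   - interaction_coordinate(r2))
                if d < 10.0:
                    expect1.add(i)
                    expect2.add(j)
        assert set(if1) == expect1 and set(if2) == expect2

    def test_irms_zero_for_native(self, native):
        assert compute_irms(native, native) == pytest.approx(0.0, abs=1e-9)

    def test_dockq_decreases_with_displacement(self, native):
        shifts = (0.5, 2.0, 6.0, 15.0, 40.0)
        values = []
        for s in shifts:
            decoy = ComplexStructure(chains=(
                native.chains[0],
                transform_chain(native.chains[1], np.eye(3),
                                np.array([0.0, 0.0, s]))))
            values.append(dockq_for_model(decoy, native).dockq)
        assert all(a > b for a, b in zip(values, values[1:]))


def _random_tables(rng, n_targets=5, n_decoys=12):
    tables = []
    for t in range(n_targets):
        rows = [(f"d{k}", float(rng.uniform(0, 1)),
                 float(rng.uniform(0, 1))) for k in range(n_decoys)]
        tables.append(RankingTable(target_id=f"T{t}", rows=rows))
    return tables


def _brute_sr(tables, N, thr):
    ok = 0
    for t in tables:
        top = sorted(t.rows, key=lambda r: -r[1])[:N]
        if any(q >= thr for _, _, q in top):
            ok += 1
    return 100.0 * ok / len(tables)


def _brute_hr(tables, N, thr):
    M = sum(q >= thr for t in tables for _, _, q in t.rows)
    H = sum(q >= thr
            for t in tables
            for _, _, q in sorted(t.rows, key=lambda r: -r[1])[:N])
    return 100.0 * H / M


class TestRankingMetrics:
    def test_hand_worked_table(self):
        rows = [("a", 0.9, 0.8), ("b", 0.8, 0.1), ("c", 0.7, 0.5),
                ("d", 0.6, 0.05)]
        t = RankingTable(target_id="T", rows=rows)
        assert success_rate([t], 1) == 100.0
        assert hit_rate([t], 1) == pytest.approx(50.0)   # 1 of 2 acceptable
        assert hit_rate([t], 3) == pytest.approx(100.0)
        bad = RankingTable(target_id="U", rows=[
            ("a", 0.9, 0.1), ("b", 0.8, 0.1), ("c", 0.1, 0.9)])
        assert success_rate([bad], 1) == 0.0
        assert success_rate([bad], 3) == 100.0
        assert success_rate([t, bad], 1) == 50.0

    def test_sr_hr_match_brute_force_on_random_tables(self, rng):
        """>= 200 randomized cases against an independent implementation."""
        cases = 0
        for _ in range(30):
            tables = _random_tables(rng, n_targets=int(rng.integers(2, 6)),
                                    n_decoys=int(rng.integers(4, 15)))
            if sum(q >= 0.23 for t in tables for _, _, q in t.rows) == 0:
                continue
            for N in (1, 2, 3, 5, 8, 10, 30):
                assert success_rate(tables, N) == pytest.approx(
                    _brute_sr(tables, N, 0.23))
                assert hit_rate(tables, N) == pytest.approx(
                    _brute_hr(tables, N, 0.23))
                cases += 2
        assert cases >= 200

    def test_sr_hr_monotone_in_n(self, rng):
        for _ in range(10):
            tables = _random_tables(rng)
            srs = [success_rate(tables, n) for n in range(1, 13)]
            hrs = [hit_rate(tables, n) for n in range(1, 13)]
            assert all(a <= b for a, b in zip(srs, srs[1:]))
            assert all(a <= b for a, b in zip(hrs, hrs[1:]))
            assert hrs[-1] == pytest.approx(100.0)   # N = all decoys

    def test_hr_no_acceptable_errors(self):
        t = RankingTable(target_id="T", rows=[("a", 0.5, 0.1)])
        with pytest.raises(ValueError, match="M = 0"):
            hit_rate([t], 1)

    def test_sr_empty_errors(self):
        with pytest.raises(ValueError):
            success_rate([], 1)


class TestCorrelationAndAuc:
    def test_perfect_and_inverted(self):
        x = np.arange(10.0)
        assert score_correlation(x, x ** 3) == pytest.approx(1.0)
        assert score_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        from scipy import stats
        a = rng.integers(0, 4, 30).astype(float)
        b = rng.integers(0, 4, 30).astype(float)
        if np.ptp(a) and np.ptp(b):
            assert score_correlation(a, b) == pytest.approx(
                stats.spearmanr(a, b).statistic)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            score_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            score_correlation([1.0, 2.0], [1.0, 2.0])

    def test_auc_hand_worked(self):
        pred = [0.9, 0.8, 0.3, 0.1]
        labels = [True, False, True, False]
        # pairs (pos, neg): (0.9>0.8), (0.9>0.1), (0.3<0.8), (0.3>0.1) -> 3/4
        assert roc_auc(pred, labels) == pytest.approx(0.75)

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 25))
            pred = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            wins = ties = total = 0
            for (pi, li), (pj, lj) in itertools.product(
                    zip(pred, labels), repeat=2):
                if li and not lj:
                    total += 1
                    wins += pi > pj
                    ties += pi == pj
            assert roc_auc(pred, labels) == pytest.approx(
                (wins + 0.5 * ties) / total)

    def test_auc_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])


class TestMinMaxNormalize:
    def test_energies_map_lowest_to_one(self):
        out = minmax_normalize([-30.0, -10.0, 10.0])
        assert out == pytest.approx([1.0, 0.5, 0.0])

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            minmax_normalize([2.0, 2.0])


class TestReports:
    def test_evaluate_dataset_keys(self, rng):
        out = evaluate_dataset(_random_tables(rng))
        assert set(out) >= {"spearman", "auc", "SR1", "HR1", "SR30", "HR30"}
        for n in (1, 5, 10, 15, 20, 25, 30):
            assert 0 <= out[f"SR{n}"] <= 100
            assert 0 <= out[f"HR{n}"] <= 100

    def test_target_tsv(self, tmp_path, native, decoy_set):
        from ifaceqe.evaluation import DockQResult
        rows, results = [], {}
        for decoy_id, _, res in decoy_set.decoys[:5]:
            rows.append((decoy_id, 0.5, res.dockq))
            results[decoy_id] = res
        table = RankingTable(target_id="T", rows=rows)
        path = tmp_path / "t.tsv"
        write_target_tsv(table, results, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("decoy\tpredicted_Q")
        assert len(lines) == 6
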
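"""Theoretical peak positions, error propagation and evolution models."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakqc.peaks import (
    SIMPLE_KARYOTYPES,
    enumerate_evolution_models,
    expected_vaf,
    multiplicity_set,
    peak_positions,
    peaks_for_karyotype,
    purity_error_from_vaf_error,
    purity_from_vaf,
    subclonal_expected_peaks,
    vaf_error_from_purity_error,
)


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "m,na,nb,purity,expected",
        [
            (1, 1, 1, 1.0, 0.5),  # heterozygous diploid, pure tumor
            (1, 2, 2, 1.0, 0.25),  # tetraploid, single copy
            (2, 2, 2, 1.0, 0.5),  # tetraploid, double copy
            (1, 2, 1, 1.0, 1 / 3),  # triploid lower peak
            (2, 2, 1, 1.0, 2 / 3),  # triploid upper peak
            (1, 2, 1, 0.9, 0.9 / 2.9),  # hand-evaluated admixed case
            (1, 1, 0, 1.0, 1.0),  # LOH in a pure tumor: every read mutant
        ],
    )
    def test_known_positions(self, m, na, nb, purity, expected):
        assert expected_vaf(m, na, nb, purity) == pytest.approx(expected)

    def test_half_purity_diploid(self):
        # with c = 1 the diploid peak sits at purity / 2
        for purity in np.linspace(0.1, 1.0, 10):
            assert expected_vaf(1, 1, 1, purity) == pytest.approx(purity / 2)

    def test_monotone_in_m_purity_ccf(self):
        base = expected_vaf(1, 2, 1, 0.5, 0.5)
        assert expected_vaf(2, 2, 1, 0.5, 0.5) > base
        assert expected_vaf(1, 2, 1, 0.6, 0.5) > base
        assert expected_vaf(1, 2, 1, 0.5, 0.6) > base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_vaf(1, 0, 0, 1.0)
        with pytest.raises(ValueError):
            expected_vaf(1, 1, 1, 0.0)
        with pytest.raises(ValueError):
            expected_vaf(0, 1, 1, 0.5)


class TestKaryotypePeaks:
    @pytest.mark.parametrize(
        "na,nb,expected_ms",
        [(1, 0, [1]), (1, 1, [1]), (2, 0, [1, 2]), (2, 1, [1, 2]), (2, 2, [1, 2]),
         (3, 2, [1, 2, 3]), (4, 2, [1, 2, 3, 4])],
    )
    def test_multiplicity_sets(self, na, nb, expected_ms):
        assert multiplicity_set(na, nb) == expected_ms
        peaks = peaks_for_karyotype(na, nb, 0.8)
        assert [p.multiplicity for p in peaks] == expected_ms
        positions = [p.vaf for p in peaks]
        assert positions == sorted(positions)
        assert all(np.diff(positions) > 0)

    def test_loh_single_peak_at_one(self):
        peaks = peaks_for_karyotype(1, 0, 1.0)
        assert len(peaks) == 1 and peaks[0].vaf == pytest.approx(1.0)


class TestErrorPropagation:
    def test_printed_vaf_errors(self):
        # triploid segment at 90% purity with a 5% purity tolerance
        assert vaf_error_from_purity_error(1, 3, 0.9, 0.05) == pytest.approx(
            0.0119, abs=5e-4
        )
        assert vaf_error_from_purity_error(2, 3, 0.9, 0.05) == pytest.approx(
            0.0238, abs=5e-4
        )
        assert vaf_error_from_purity_error(1, 3, 0.9, 0.0) == 0.0

    @pytest.mark.parametrize(
        "v,m,p,expected",
        [(0.5, 1, 2, 1.0), (0.45, 1, 2, 0.9), (1 / 3, 1, 3, 1.0)],
    )
    def test_purity_inversion(self, v, m, p, expected):
        assert purity_from_vaf(v, m, p) == pytest.approx(expected)

    def test_roundtrip_on_grid(self):
        # propagating a purity error to VAF space and back returns it exactly
        for m, p, purity, eps in itertools.product(
            (1, 2, 3), (1, 2, 3, 4), (0.2, 0.5, 0.8, 0.95), (0.01, 0.05, 0.1)
        ):
            v = m * purity / (2 * (1 - purity) + purity * p)
            dv = vaf_error_from_purity_error(m, p, purity, eps)
            assert purity_error_from_vaf_error(v, dv, m, p) == pytest.approx(
                eps, rel=1e-12
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        m=st.integers(1, 4),
        p=st.integers(1, 6),
        purity=st.floats(0.05, 1.0),
        eps=st.floats(1e-4, 0.2),
    )
    def test_roundtrip_property(self, m, p, purity, eps):
        v = m * purity / (2 * (1 - purity) + purity * p)
        dv = vaf_error_from_purity_error(m, p, purity, eps)
        assert purity_error_from_vaf_error(v, dv, m, p) == pytest.approx(
            eps, rel=1e-9
        )


# ---------------------------------------------------------------------------
# Evolution models
# ---------------------------------------------------------------------------


def _oracle_models(state1, state2, ancestor=(1, 1)):
    """Brute-force search over allele-labelled copy-state graphs.

    Independent of the implementation: plain breadth-first enumeration of
    event sequences, with mutations propagated as explicit copy markers.
    """

    def orientations(s):
        a, b = (int(x) for x in s.split(":"))
        return {(a, b), (b, a)}

    def moves(state):
        a, b = state
        out = []
        if a >= 1 and a < 4:
            out.append((a + 1, b))
        if b >= 1 and b < 4:
            out.append((a, b + 1))
        if a >= 1:
            out.append((a - 1, b))
        if b >= 1:
            out.append((a, b - 1))
        if a <= 2 and b <= 2:
            out.append((2 * a, 2 * b))
        return out

    def all_shortest(src, dst):
        if src == dst:
            return [[src]]
        layer = {src: [[src]]}
        seen = {src}
        for _ in range(8):
            new = {}
            for s, paths in layer.items():
                for t in moves(s):
                    if t in seen:
                        continue
                    new.setdefault(t, []).extend(p + [t] for p in paths)
            if dst in new:
                return new[dst]
            seen |= set(new)
            layer = new
            if not layer:
                return []
        return []

    def mult_outcomes(path_states):
        """Per-epoch achievable per-allele end counts along a state path.

        Returns for each epoch t the set of (end_a_count, end_b_count)
        multiplicities a single marked copy can reach, per allele.  States
        are abstract; copy choices are enumerated recursively.
        """
        # concrete copies: list of (allele, marked) tuples
        def expand(copies, states):
            if len(states) == 1:
                return [copies]
            cur, nxt = states[0], states[1]
            da, db = nxt[0] - cur[0], nxt[1] - cur[1]
            outs = []
            if (da, db) == (cur[0], cur[1]):  # doubling
                outs.extend(expand(copies + copies, states[1:]))
            else:
                allele = 0 if da != 0 else 1
                delta = da if da != 0 else db
                idxs = [i for i, c in enumerate(copies) if c[0] == allele]
                for i in idxs:
                    if delta > 0:
                        outs.extend(expand(copies + [copies[i]], states[1:]))
                    else:
                        outs.extend(
                            expand(copies[:i] + copies[i + 1:], states[1:])
                        )
            return outs

        per_epoch = []
        for t in range(len(path_states)):
            a_t, b_t = path_states[t]
            start = [(0, i == 0) for i in range(a_t)] + [
                (1, i == 0) for i in range(b_t)
            ]
            # mark each copy in turn
            epoch_outcomes = set()
            for marked in range(a_t + b_t):
                copies = [
                    (al, j == marked)
                    for j, (al, _) in enumerate(start)
                ]
                for final in expand(copies, path_states[t:]):
                    m = sum(1 for c in final if c[1])
                    allele = copies[marked][0]
                    epoch_outcomes.add((allele, m))
            per_epoch.append(epoch_outcomes)
        return per_epoch

    results = set()
    # branching
    seen_b = set()
    branch_cands = []
    for o1 in orientations(state1):
        for o2 in orientations(state2):
            p1s = all_shortest(ancestor, o1)
            p2s = all_shortest(ancestor, o2)
            if not p1s or not p2s:
                continue
            canon = min((o1, o2), ((o1[1], o1[0]), (o2[1], o2[0])))
            branch_cands.append((len(p1s[0]) + len(p2s[0]), canon, o1, o2, p1s, p2s))
    if branch_cands:
        best = min(c[0] for c in branch_cands)
        for length, canon, o1, o2, p1s, p2s in branch_cands:
            if length != best or canon in seen_b:
                continue
            seen_b.add(canon)
            for p1, p2 in itertools.product(p1s, p2s):
                shared = set()
                for allele in (0, 1):
                    m1 = {m for al, m in mult_outcomes(p1)[0] if al == allele}
                    m2 = {m for al, m in mult_outcomes(p2)[0] if al == allele}
                    for a, b in itertools.product(m1, m2):
                        if a + b > 0:
                            shared.add((a, b))
                priv1 = {m for e in mult_outcomes(p1) for _, m in e if m > 0}
                priv2 = {m for e in mult_outcomes(p2) for _, m in e if m > 0}
                results.add(
                    ("branching", frozenset(shared), frozenset(priv1), frozenset(priv2))
                )
    # linear, both directions
    for first, second, swap in ((state1, state2, False), (state2, state1, True)):
        cands = []
        for o1 in orientations(first):
            p1s = all_shortest(ancestor, o1)
            if not p1s:
                continue
            for o2 in orientations(second):
                p12s = all_shortest(o1, o2)
                if not p12s:
                    continue
                cands.append((len(p1s[0]) + len(p12s[0]), p1s, p12s))
        if not cands:
            continue
        best = min(c[0] for c in cands)
        for length, p1s, p12s in cands:
            if length != best:
                continue
            for p1, p12 in itertools.product(p1s, p12s):
                full = p1 + p12[1:]
                split = len(p1) - 1
                shared = set()
                outcomes = mult_outcomes(full)
                for t in range(split + 1):
                    a_t, b_t = full[t]
                    for allele in (0, 1):
                        # multiplicity in tip clone from marking at epoch t
                        m2s = {m for al, m in outcomes[t] if al == allele}
                        # multiplicity in the intermediate clone: marking at
                        # epoch t of the truncated path ancestor -> o1
                        trunc = mult_outcomes(full[t : split + 1])
                        m1s = {m for al, m in trunc[0] if al == allele}
                        for a, b in itertools.product(m1s, m2s):
                            if a + b > 0:
                                shared.add((a, b))
                priv_mid = {1} if full[split][0] + full[split][1] > 0 else set()
                tail = mult_outcomes(full[split:])
                priv_tip = {m for e in tail for _, m in e if m > 0}
                pm1, pm2 = (priv_tip, priv_mid) if swap else (priv_mid, priv_tip)
                sh = {(b, a) for a, b in shared} if swap else shared
                results.add(
                    ("linear", frozenset(sh), frozenset(pm1), frozenset(pm2))
                )
    return results


@pytest.mark.parametrize(
    "s1,s2", list(itertools.combinations_with_replacement(sorted(SIMPLE_KARYOTYPES), 2))
)
def test_models_match_bruteforce(s1, s2):
    """Structured enumeration equals an independent brute-force search."""
    impl = {
        (
            m.topology,
            m.shared_multiplicities,
            frozenset(m.private_multiplicities[0]),
            frozenset(m.private_multiplicities[1]),
        )
        for m in enumerate_evolution_models(s1, s2)
    }
    oracle = _oracle_models(s1, s2)
    assert impl == oracle


class TestModelCatalogue:
    def test_trisomy_cnloh_pair(self):
        models = enumerate_evolution_models("2:1", "2:0")
        labels = sorted(m.describe() for m in models)
        assert len(models) == 3
        assert sum(m.topology == "branching" for m in models) == 2
        linear = [m for m in models if m.topology == "linear"]
        assert len(linear) == 1
        # the CNLOH subclone must descend from the trisomy, never vice versa
        assert linear[0].describe() == "AB -> AAB -> AA"

    def test_lost_allele_never_regained(self):
        # no linear chain can evolve a trisomy out of a CNLOH state
        models = enumerate_evolution_models("2:0", "2:1")
        for m in models:
            if m.topology == "linear":
                intermediate = m.clone2 if m.clone1_events else m.clone1
                assert intermediate != (2, 0) and intermediate != (0, 2)

    def test_diploid_loh_pair_equivalent_topologies(self):
        models = enumerate_evolution_models("1:1", "1:0")
        topologies = {m.topology for m in models}
        assert topologies == {"linear", "branching"}
        peak_sets = {
            tuple(peak_positions(subclonal_expected_peaks(m, 0.75, 0.25, 0.8), 6))
            for m in models
        }
        assert len(peak_sets) == 1  # linear and branching are peak-equivalent


class TestSubclonalPeaks:
    def setup_method(self):
        self.models = {
            m.describe(): m for m in enumerate_evolution_models("2:1", "2:0")
        }

    def _peaks(self, label):
        return subclonal_expected_peaks(self.models[label], 0.75, 0.25, 0.8)

    def test_mirrored_branching_worked_example(self):
        got = {round(p.vaf, 2) for p in self._peaks("AB -> AAB | BB")}
        assert got == {0.38, 0.46, 0.23, 0.15, 0.08}

    def test_same_allele_branching_worked_example(self):
        shared = [
            p
            for p in self._peaks("AB -> AAB | AA")
            if p.origin == "subclonal_shared"
        ]
        assert [round(p.vaf, 2) for p in shared] == [0.62]  # 1.6 / 2.6
        assert shared[0].vaf == pytest.approx(1.6 / 2.6)

    def test_linear_worked_example(self):
        shared = sorted(
            round(p.vaf, 2)
            for p in self._peaks("AB -> AAB -> AA")
            if p.origin == "subclonal_shared"
        )
        assert shared == [0.31, 0.62]
        private = sorted(
            round(p.vaf, 2)
            for p in self._peaks("AB -> AAB -> AA")
            if p.origin == "subclonal_private"
        )
        assert private == [0.08, 0.23]

    def test_mirrored_triploid_pseudobulk(self):
        models = enumerate_evolution_models("2:1", "1:2")
        mirrored = next(m for m in models if m.describe() == "AB -> AAB | ABB")
        peaks = subclonal_expected_peaks(mirrored, 0.58, 0.42, 1.0)
        shared = {p.multiplicity: p.vaf for p in peaks if p.origin == "subclonal_shared"}
        assert shared[(1, 2)] == pytest.approx((0.58 + 2 * 0.42) / 3)
        assert shared[(2, 1)] == pytest.approx((2 * 0.58 + 0.42) / 3)

    def test_same_allele_triploid_pseudobulk(self):
        models = enumerate_evolution_models("2:1", "2:1")
        same = next(m for m in models if m.describe() == "AB -> AAB | AAB")
        peaks = subclonal_expected_peaks(same, 0.58, 0.42, 1.0)
        shared = sorted(
            p.vaf for p in peaks if p.origin == "subclonal_shared"
        )
        assert shared == pytest.approx([1 / 3, 2 / 3])

    def test_continuity_to_clonal_limit(self):
        # as the first clone takes over, peaks converge to its clonal peaks
        model = self.models["AB -> AAB | BB"]
        peaks = subclonal_expected_peaks(model, 1 - 1e-9, 1e-9, 0.8)
        clonal = {round(p.vaf, 6) for p in peaks_for_karyotype(2, 1, 0.8)}
        got = {round(p.vaf, 6) for p in peaks}
        assert clonal <= got

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            subclonal_expected_peaks(self.models["AB -> AAB | BB"], 0.7, 0.4, 0.8)
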
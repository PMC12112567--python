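"""Stochastic repeat-chain model: exact probabilities, invariants, domains."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsatdyn import (
    RepeatChain, SpatialParameters, m_domains, mean_field_increments, ode_rhs,
    phase_grid, rna_qssa, run, step, transcript_level,
)
from hsatdyn.spatial import _cooperative_eligibility, ode_equivalent_parameters

# effectively disables insertions/deletions (rates must be positive)
NO_INDEL = dict(sigma=1e-300, gamma=1e-300)


# -- single-step behavior ------------------------------------------------

def test_all_methylated_chain_is_frozen_without_demethylation():
    p = SpatialParameters(mu=0.0, **NO_INDEL)
    chain = RepeatChain(np.ones(50, dtype=bool), seed=1)
    out = step(chain, p)
    assert out.states.all() and out.copy_number == 50
    assert out.generation == 1


def test_all_methylated_chain_skips_insertion_without_hosts():
    # high insertion pressure but no U site to host the new copy
    p = SpatialParameters(mu=0.0, sigma=10.0, gamma=1e-300)
    chain = RepeatChain(np.ones(30, dtype=bool), seed=2)
    out = step(chain, p)
    assert out.copy_number == 30
    assert out.last_events["insertions"] == 0


def test_all_unmethylated_absorbing_without_spontaneous_methylation():
    p = SpatialParameters(eta=0.0, **NO_INDEL)
    chain = RepeatChain(np.zeros(60, dtype=bool), seed=3)
    for _ in range(20):
        chain = step(chain, p)
    assert not chain.states.any()


def test_empty_chain_flags_extinction():
    p = SpatialParameters()
    chain = RepeatChain(np.zeros(0, dtype=bool), seed=4)
    out = step(chain, p)
    assert out.extinct and out.copy_number == 0


def test_single_step_flip_probabilities_match_exact_enumeration():
    """Frequencies of per-site transitions over many replicates against the
    exact per-site probabilities computed by hand for a fixed length-12
    chain (indels disabled so sites stay aligned)."""
    pattern = np.array([0, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0], dtype=bool)
    p = SpatialParameters(eta=0.05, phi=0.3, mu=0.2, **NO_INDEL)
    # exact: M stays M w.p. 1-mu; U becomes M w.p. eta, or the composed
    # probability when another site within two positions carries M
    def p_methylated(i):
        if pattern[i]:
            return 1 - p.mu
        near = [j for j in range(12) if j != i and abs(i - j) <= 2]
        if any(pattern[j] for j in near):
            return 1 - (1 - p.eta) * (1 - p.phi)
        return p.eta

    p_m = np.array([p_methylated(i) for i in range(12)])
    n = 30_000
    chain = RepeatChain(pattern, seed=11)
    counts = np.zeros(12)
    for _ in range(n):
        counts += step(chain, p).states
    freq = counts / n
    se = np.sqrt(p_m * (1 - p_m) / n)
    assert np.all(np.abs(freq - p_m) < 3 * se + 1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=255), st.integers(min_value=1, max_value=8))
def test_cooperative_eligibility_matches_brute_force(bits, length):
    states = np.array([(bits >> i) & 1 for i in range(length)], dtype=bool)
    got = _cooperative_eligibility(states, 2)
    want = np.array([
        any(states[j] for j in range(length) if j != i and abs(i - j) <= 2)
        for i in range(length)
    ])
    assert np.array_equal(got, want)


def test_global_eligibility():
    states = np.zeros(10, dtype=bool)
    assert not _cooperative_eligibility(states, "global").any()
    states[7] = True
    assert _cooperative_eligibility(states, "global").all()


# -- runs ----------------------------------------------------------------

def test_run_is_deterministic_given_seed():
    p = SpatialParameters()
    a = run(RepeatChain.random(400, 0.6, seed=5), p, 60)
    b = run(RepeatChain.random(400, 0.6, seed=5), p, 60)
    assert a.stats.equals(b.stats)
    assert np.array_equal(a.final_chain.states, b.final_chain.states)


def test_serialization_round_trip_resumes_identically():
    """A chain serialized mid-run (states + RNG stream position) must
    continue exactly like the original."""
    p = SpatialParameters()
    chain = RepeatChain.random(300, 0.5, seed=9)
    for _ in range(10):
        chain = step(chain, p)
    resumed = RepeatChain.from_dict(chain.to_dict())
    tail_a, tail_b = chain, resumed
    for _ in range(5):
        tail_a = step(tail_a, p)
        tail_b = step(tail_b, p)
    assert np.array_equal(tail_a.states, tail_b.states)


def test_structural_conservation_and_stats():
    p = SpatialParameters()
    out = run(RepeatChain.random(500, 0.7, seed=6), p, 80)
    s = out.stats
    assert np.all(s.n_methylated <= s.copy_number)
    assert np.all(s.n_methylated >= 0)
    f = s.methylated_fraction.dropna()
    assert np.allclose(f, s.n_methylated[f.index] / s.copy_number[f.index])


def test_low_methylation_rates_lose_all_methylation():
    p = SpatialParameters(eta=1e-4, phi=1e-3, **NO_INDEL)
    out = run(RepeatChain.random(800, 0.6, seed=7), p, 150)
    assert out.stats.methylated_fraction.iloc[-1] < 0.02


def test_default_rates_sustain_high_methylation():
    out = run(RepeatChain.random(2000, 0.68, seed=8), SpatialParameters(), 120)
    tail = out.stats.methylated_fraction.iloc[-30:]
    assert tail.mean() > 0.5


def test_rle_round_trip():
    chain = RepeatChain.random(200, 0.4, seed=10)
    again = RepeatChain.from_rle(chain.to_rle())
    assert np.array_equal(chain.states, again.states)
    assert RepeatChain.from_rle("").copy_number == 0
    with pytest.raises(ValueError):
        RepeatChain.from_rle("M3X2")


# -- domains -------------------------------------------------------------

@pytest.mark.parametrize("rle,expected_sizes", [
    ("M4", [4]),
    ("M4U1M4", [9]),               # 1 U in 9 sites: 11% <= 20%
    ("M1U3M1", [1, 1]),            # 60% U gap: two singleton domains
    ("U5", []),
])
def test_m_domain_examples(rle, expected_sizes):
    domains, mean_size = m_domains(RepeatChain.from_rle(rle))
    assert [d[2] for d in domains] == expected_sizes
    if expected_sizes:
        assert mean_size == pytest.approx(np.mean(expected_sizes))
    else:
        assert np.isnan(mean_size)


def _oracle_domains(states, tol):
    """Independent greedy merge over M runs (re-derived from scratch)."""
    runs = []
    i = 0
    states = list(states)
    while i < len(states):
        if states[i]:
            j = i
            while j < len(states) and states[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return []
    merged = [runs[0]]
    m_in_cur = runs[0][1] - runs[0][0]
    for a, b in runs[1:]:
        s, e = merged[-1]
        span = b - s
        m_new = m_in_cur + (b - a)
        if (span - m_new) / span <= tol:
            merged[-1] = (s, b)
            m_in_cur = m_new
        else:
            merged.append((a, b))
            m_in_cur = b - a
    return [e - s for s, e in merged]


@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=0, max_size=20),
       st.sampled_from([0.0, 0.1, 0.2, 0.4]))
def test_m_domains_match_independent_oracle(states, tol):
    domains, mean_size = m_domains(np.array(states, dtype=bool), tol)
    want = _oracle_domains(states, tol)
    assert [d[2] for d in domains] == want
    if want:
        assert mean_size == pytest.approx(np.mean(want))


def test_m_domains_rejects_bad_tolerance():
    with pytest.raises(ValueError):
        m_domains(np.ones(3, dtype=bool), 1.0)


# -- phase grid ----------------------------------------------------------

def test_phase_grid_zero_rates_cell_loses_methylation():
    df = phase_grid([0.0], [0.0], SpatialParameters(**NO_INDEL),
                    replicates=2, horizon=60, seed=0, chain_length=400)
    assert df.methylated_fraction.iloc[0] < 0.02


def test_phase_grid_fraction_monotone_in_spontaneous_rate():
    df = phase_grid([0.002, 0.02, 0.2], [0.1], SpatialParameters(),
                    replicates=3, horizon=80, seed=1, chain_length=600,
                    init_fraction=0.5)
    f = df.sort_values("eta").methylated_fraction.to_numpy()
    assert np.all(np.diff(f) > -0.05)  # non-decreasing within noise
    assert f[-1] > f[0]


def test_phase_grid_default_rates_sustain_methylation():
    df = phase_grid([0.01], [0.2], SpatialParameters(),
                    replicates=2, horizon=100, seed=2, chain_length=1500,
                    init_fraction=0.68)
    assert df.methylated_fraction.iloc[0] > 0.3
    assert df.extinctions.iloc[0] == 0


# -- mean-field correspondence ------------------------------------------

def test_mean_field_cn_increment_equals_ode_copy_equation():
    """The analytic expected copy-number increment is algebraically the ODE
    copy-number equation under the QSSA transcript level."""
    sp = SpatialParameters(neighborhood_radius="global")
    ode_p = ode_equivalent_parameters(sp)
    for n_m, cn in [(0, 100), (300, 2000), (900, 1200)]:
        _, d_cn = mean_field_increments(n_m, cn, sp)
        x1 = rna_qssa(n_m, cn, ode_p)
        assert x1 == pytest.approx(transcript_level(n_m, cn, sp), rel=1e-14)
        assert d_cn == pytest.approx(ode_rhs((x1, n_m, cn), ode_p)[2], rel=1e-12)


def test_mean_field_nm_increment_reduces_to_ode_without_cooperativity():
    sp = SpatialParameters(phi=0.0, neighborhood_radius="global")
    ode_p = ode_equivalent_parameters(sp.replace(phi=1e-300))
    for n_m, cn in [(10, 500), (400, 900)]:
        d_nm, _ = mean_field_increments(n_m, cn, sp)
        want = ode_p.eta * (cn - n_m) - ode_p.mu * n_m
        assert d_nm == pytest.approx(want, rel=1e-12)


def test_simulated_increments_match_mean_field_at_large_cn():
    """Monte-Carlo one-step increments of (nM, CN) under global
    cooperativity against the analytic expectation, within 3 SE."""
    sp = SpatialParameters(neighborhood_radius="global")
    cn, frac = 2000, 0.3
    chain = RepeatChain.random(cn, frac, seed=13)
    n_m = chain.n_methylated
    want_nm, want_cn = mean_field_increments(n_m, cn, sp)
    reps = 400
    d_nm = np.empty(reps)
    d_cn = np.empty(reps)
    for k in range(reps):
        out = step(chain, sp)
        d_nm[k] = out.n_methylated - n_m
        d_cn[k] = out.copy_number - cn
    for sample, want in ((d_nm, want_nm), (d_cn, want_cn)):
        se = sample.std(ddof=1) / np.sqrt(reps)
        assert abs(sample.mean() - want) < 3 * se


def test_copy_number_feedback_direction():
    """Low-methylation chains transcribe and insert more than matched
    high-methylation chains: the U accumulation drives copy gain."""
    sp = SpatialParameters()
    lo = run(RepeatChain.random(2000, 0.2, seed=21), sp, 40)
    hi = run(RepeatChain.random(2000, 0.9, seed=21), sp, 40)
    assert lo.stats.insertions.mean() > hi.stats.insertions.mean()
    assert lo.stats.copy_number.iloc[-1] > hi.stats.copy_number.iloc[-1]
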
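"""Flow-run simulator: flowgrams, phasing, trace synthesis, movie rendering."""

import itertools

import numpy as np
import pytest

from kinflow import kinetics as kin
from kinflow import simulate as sim
from kinflow.errors import InputError


class TestExpectedFlowgram:
    @pytest.mark.parametrize(
        "seq,order,n,expected",
        [
            ("GAAC", "GTAC", 4, [1, 0, 2, 1]),
            ("GAAC", "GCAT", 4, [1, 0, 2, 0]),
            ("TTTT", "GTAC", 4, [0, 4, 0, 0]),
            ("ACGT", "A", 3, [1, 0, 0]),
        ],
    )
    def test_hand_decoded_cases(self, seq, order, n, expected):
        assert sim.expected_flowgram(seq, order, n).tolist() == expected

    def test_absent_base_flows_are_zero(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACG"), size=30))
            fg = sim.expected_flowgram(seq, "GTAC", 16)
            t_flows = [i for i in range(16) if "GTAC"[i % 4] == "T"]
            assert all(fg[i] == 0 for i in t_flows)

    def test_total_bases_bounded_by_length(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=25))
            fg = sim.expected_flowgram(seq, "GTAC", 44)
            assert fg.sum() <= len(seq)

    def test_mean_bases_for_44_flows_near_28(self, rng):
        # uniform random templates, 44 flows, G,T,A,C order: the cyclic-speed
        # estimate predicts roughly 28 bases on average
        totals = [
            sim.expected_flowgram(
                "".join(rng.choice(list("ACGT"), size=200)), "GTAC", 44
            ).sum()
            for _ in range(10_000)
        ]
        assert np.mean(totals) == pytest.approx(28, abs=1.5)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(InputError):
            sim.expected_flowgram("ACGN", "GTAC", 4)
        with pytest.raises(InputError):
            sim.expected_flowgram("", "GTAC", 4)


class TestApplyPhasing:
    def test_zero_phasing_keeps_delta(self):
        seq = "GGATC"
        dist = np.zeros(6)
        dist[0] = 1.0
        out = sim.apply_phasing(dist, seq, "G", sim.PhasingParams())
        assert out[2] == 1.0 and out.sum() == pytest.approx(1.0)

    def test_full_lag_never_advances(self):
        seq = "GGATC"
        dist = np.zeros(6)
        dist[0] = 1.0
        p = sim.PhasingParams(p_lag=0.999999)
        out = sim.apply_phasing(dist, seq, "G", sim.PhasingParams(p_lag=0.5))
        assert out[0] == pytest.approx(0.5)
        out = sim.apply_phasing(dist, seq, "G", p)
        assert out[0] == pytest.approx(0.999999)

    def test_mass_conserved(self, rng):
        seq = "GATTACA"
        dist = rng.dirichlet(np.ones(8))
        out = sim.apply_phasing(dist, seq, "T", sim.PhasingParams(p_lag=0.1, p_lead=0.05))
        assert abs(out.sum() - 1.0) < 1e-12

    def test_matches_exhaustive_enumeration_on_six_base_template(self):
        # brute-force oracle: enumerate every per-molecule lag/lead outcome
        # tree over 6 flows and accumulate exact path probabilities
        seq = "GGTACC"
        flows = ["G", "T", "A", "C", "G", "T"]
        ph = sim.PhasingParams(p_lag=0.2, p_lead=0.1)

        def enumerate_paths(pos, flow_idx, prob, acc):
            if flow_idx == len(flows):
                acc[pos] += prob
                return
            base = flows[flow_idx]
            run = 0
            while pos + run < len(seq) and seq[pos + run] == base:
                run += 1
            if run > 0:
                enumerate_paths(pos, flow_idx + 1, prob * ph.p_lag, acc)
                enumerate_paths(pos + run, flow_idx + 1, prob * (1 - ph.p_lag), acc)
            elif pos < len(seq):
                enumerate_paths(pos + 1, flow_idx + 1, prob * ph.p_lead, acc)
                enumerate_paths(pos, flow_idx + 1, prob * (1 - ph.p_lead), acc)
            else:
                enumerate_paths(pos, flow_idx + 1, prob, acc)

        oracle = np.zeros(len(seq) + 1)
        enumerate_paths(0, 0, 1.0, oracle)

        dist = np.zeros(len(seq) + 1)
        dist[0] = 1.0
        for base in flows:
            dist = sim.apply_phasing(dist, seq, base, ph)
        assert np.allclose(dist, oracle, atol=1e-12)

    def test_per_molecule_sampling_agrees_with_matrix(self):
        seq = "GGTACC"
        flows = ["G", "T", "A", "C"]
        ph = sim.PhasingParams(p_lag=0.3, p_lead=0.1)
        dist = np.zeros(len(seq) + 1)
        dist[0] = 1.0
        for base in flows:
            dist = sim.apply_phasing(dist, seq, base, ph)
        emp = sim.phasing_per_molecule(seq, flows, ph, n_molecules=20_000, seed=7)
        assert np.abs(emp - dist).max() < 0.02


class TestTraceSimulation:
    def test_single_one_mer_flow_is_scaled_kinetics_course(self):
        # composition identity: no noise, no phasing, unit copy number, no
        # dead frames -> trace == photon_scale x %SC from the kinetics model
        templates = sim.TemplateSet.uniform("GAA", 1)
        program = sim.FlowProgram(
            flows=(sim.Flow("G", 100.0),), frames_per_flow=200, dead_frames=0
        )
        noise = sim.NoiseParams(photon_scale=500.0, background=0.0)
        run = sim.simulate_cluster_flow_traces(templates, program, noise=noise, seed=0)
        rates_c, _ = sim.sequencing_rate_constants()
        mix = kin.ReactionMix(sim.SEQ_ENZYME_TOTAL, sim.SEQ_DNA_TOTAL, 100.0)
        t = np.arange(200) / 10.0
        tc = kin.simulate_timecourse(rates_c, mix, t, mode="flow")
        assert np.allclose(run.traces[0, 0], 500.0 * tc.percent_sc_series, rtol=1e-9)

    def test_truth_flowgram_equals_expected_flowgram(self, small_monotemplate_run):
        run = small_monotemplate_run
        for c, seq in enumerate(run.templates.sequences):
            expected = sim.expected_flowgram(seq, run.program.bases, len(run.program.flows))
            assert np.array_equal(run.truth_flowgrams[c], expected)

    def test_integrated_counts_increase_with_homopolymer_length(self):
        # 0-, 1-, 2-, 3-mer A templates under a single A flow
        program = sim.FlowProgram.cyclic("A", 1, frames_per_flow=200)
        noise = sim.NoiseParams(background=0.0)
        window = slice(program.dead_frames, 150)
        integrals = []
        for seq in ["C", "AC", "AAC", "AAAC"]:
            run = sim.simulate_cluster_flow_traces(
                sim.TemplateSet.uniform(seq, 1), program, noise=noise, seed=0
            )
            integrals.append(run.traces[0, 0, window].sum())
        assert np.all(np.diff(integrals) > 0)

    def test_mismatch_flow_low_amplitude_plateau(self):
        # a flow of a base the template cannot extend: low flat trace, max
        # amplitude well below the correct 1-mer's
        program = sim.FlowProgram.cyclic("A", 1, frames_per_flow=200)
        noise = sim.NoiseParams(background=0.0)
        run_mm = sim.simulate_cluster_flow_traces(
            sim.TemplateSet.uniform("C", 1), program, noise=noise, seed=0
        )
        run_ok = sim.simulate_cluster_flow_traces(
            sim.TemplateSet.uniform("AC", 1), program, noise=noise, seed=0
        )
        live = slice(program.dead_frames, None)
        mm, ok = run_mm.traces[0, 0, live], run_ok.traces[0, 0, live]
        assert mm.max() < ok.max() / 2
        assert np.ptp(mm[20:]) < 0.05 * mm.max()  # plateau

    def test_photon_count_linear_in_copy_number(self):
        program = sim.FlowProgram.cyclic("GCAT", 4, frames_per_flow=150)
        noise = sim.NoiseParams(background=0.0)
        totals = []
        copies = [1.0, 3.0, 10.0]
        for cn in copies:
            run = sim.simulate_cluster_flow_traces(
                sim.TemplateSet.uniform("CTAG", 2, copy_number=cn),
                program,
                noise=noise,
                seed=0,
            )
            totals.append(run.traces.sum())
        totals = np.array(totals)
        assert np.allclose(totals / totals[0], np.array(copies), rtol=1e-9)

    def test_seed_reproducibility(self):
        noise = sim.NoiseParams(read_noise_sigma=5.0, shot_noise=True)
        a = sim.make_monotemplate_run(seed=3, n_clusters=3, noise=noise)
        b = sim.make_monotemplate_run(seed=3, n_clusters=3, noise=noise)
        assert np.array_equal(a.traces, b.traces)


class TestRenderMovie:
    def _tiny_run(self, n_clusters=1, template="AC"):
        program = sim.FlowProgram.cyclic("A", 1, frames_per_flow=60, dead_frames=10)
        return sim.simulate_cluster_flow_traces(
            sim.TemplateSet.uniform(template, n_clusters),
            program,
            noise=sim.NoiseParams(background=20.0),
            seed=0,
        )

    def test_zero_traces_render_background(self):
        run = self._tiny_run()
        run.traces[:] = run.noise.background
        layout = sim.SpotLayout(centers=np.array([[12.0, 12.0]]), image_shape=(24, 24))
        stacks = sim.render_movie(run, layout)
        assert np.allclose(stacks[0], run.noise.background, atol=1e-5)

    def test_patch_sum_recovers_trace_up_to_psf_norm(self):
        # single spot, no noise: background-subtracted sum over a generous
        # patch equals trace x (2 pi sigma^2) to high accuracy
        run = self._tiny_run()
        sigma = 1.2
        layout = sim.SpotLayout(
            centers=np.array([[16.0, 16.0]]), image_shape=(33, 33), psf_sigma=sigma
        )
        stacks = sim.render_movie(run, layout)
        patch = stacks[0][:, 10:23, 10:23].astype(float)
        sums = (patch - run.noise.background).sum(axis=(1, 2))
        expected = (run.traces[0, 0] - run.noise.background) * 2 * np.pi * sigma**2
        scale = max(np.abs(expected).max(), 1.0)
        assert np.abs(sums - expected).max() / scale < 1e-3

    def test_two_spots_ten_px_apart_independent(self):
        run = self._tiny_run(n_clusters=2)
        run.traces[1] = run.noise.background  # second spot dark
        layout = sim.SpotLayout(
            centers=np.array([[16.0, 11.0], [16.0, 21.0]]), image_shape=(33, 33)
        )
        stacks = sim.render_movie(run, layout)
        # 7x7 patch around the dark spot: cross-talk below 0.1% of bright sum
        bright = (stacks[0][:, 13:20, 8:15] - run.noise.background).sum()
        dark = (stacks[0][:, 13:20, 18:25] - run.noise.background).sum()
        assert abs(dark) < 1e-3 * abs(bright)

    def test_overlapping_centers_warn(self):
        run = self._tiny_run(n_clusters=2)
        layout = sim.SpotLayout(
            centers=np.array([[12.0, 12.0], [12.0, 12.0]]), image_shape=(24, 24)
        )
        with pytest.warns(UserWarning, match="overlapping"):
            sim.render_movie(run, layout)


class TestReferenceTools:
    def test_degenerate_composition_homopolymer(self):
        seq = sim.make_reference(50, (1.0, 0.0, 0.0, 0.0), seed=0)
        assert seq == "A" * 50

    def test_invalid_composition_rejected(self):
        with pytest.raises(InputError):
            sim.make_reference(50, (0.0, 0.0, 0.0), seed=0)

    def test_seed_reproducibility(self):
        a = sim.make_reference(200, (0.25, 0.25, 0.25, 0.25), seed=5)
        b = sim.make_reference(200, (0.25, 0.25, 0.25, 0.25), seed=5)
        assert a == b
        c = sim.fragment_reference(a, 30, 10, seed=6)
        d = sim.fragment_reference(a, 30, 10, seed=6)
        assert c.sequences == d.sequences

    def test_nmer_distribution_follows_geometric_law(self):
        # uniform composition: homopolymer length is geometric with p = 3/4
        seq = sim.make_reference(100_000, (0.25, 0.25, 0.25, 0.25), seed=9)
        lengths = [len(list(g)) for _, g in itertools.groupby(seq)]
        lengths = np.array(lengths)
        total = lengths.size
        for n, expected in [(1, 0.75), (2, 0.1875), (3, 0.046875)]:
            assert (lengths == n).sum() / total == pytest.approx(expected, abs=0.01)

    def test_fragment_length_and_prefix(self):
        ref = sim.make_reference(500, (0.25, 0.25, 0.25, 0.25), seed=1)
        ts = sim.fragment_reference(ref, 40, 25, seed=2, prefix="GTACGTAC")
        assert all(len(s) == 48 for s in ts.sequences)
        assert all(s.startswith("GTACGTAC") for s in ts.sequences)

    def test_fragment_requires_longer_reference(self):
        with pytest.raises(InputError):
            sim.fragment_reference("ACGT", 10, 5, seed=0)
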
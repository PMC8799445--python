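"""Worklist expansion, batching, EDF scheduling, CSV dialect and simulator."""

import copy
import io

import pytest

from lfadev.design import DeckLayout, DesignSpec, FactorSpec, enumerate_conditions, split_into_runs
from lfadev.mixplan import StockSolution, plan_mixture
from lfadev.schedule import (
    InfeasibleSchedule,
    Protocol,
    ProtocolStep,
    RobotConfig,
    Transfer,
    Worklist,
    batch_transfers,
    build_worklist,
    expand_protocol,
    read_worklist_csv,
    schedule_run,
    simulate_worklist,
    write_worklist_csv,
)
from lfadev.synth import random_schedule_case


def make_run(n_strips, cap=96):
    design = DesignSpec(factors=(FactorSpec("strip", tuple(range(n_strips))),))
    deck = DeckLayout(holders=(("H1", cap),), cassette_holders=frozenset({"H1"}))
    return split_into_runs(enumerate_conditions(design), deck)[0]


def flat_protocol(n_liquid=2, image_at=1800, durations=10, tol=60):
    steps = [
        ProtocolStep(i, "dispense_reagent" if i < n_liquid - 1 else "dispense_sample",
                     reagent_ref="reagent", volume=10.0, duration=durations)
        for i in range(n_liquid)
    ]
    if image_at is not None:
        steps.append(ProtocolStep(n_liquid, "image",
                                  target_time_after_sample=image_at, duration=durations))
    return Protocol(name="flat", steps=tuple(steps), imaging_tolerance_s=tol)


SOURCES = {"reagent": ("stocks", "reagent")}


class TestExpand:
    def test_each_condition_step_pair_yields_one_event(self, small_run,
                                                       three_step_protocol,
                                                       small_sources):
        transfers = expand_protocol(small_run, three_step_protocol, small_sources)
        liquid = [t for t in transfers if not t.is_image]
        images = [t for t in transfers if t.is_image]
        assert len(liquid) == 8 * 2 and len(images) == 8
        pairs = {(t.condition_id, t.step_index) for t in transfers}
        assert len(pairs) == 8 * 3

    def test_two_conditions_three_steps(self, three_step_protocol):
        run = make_run(2)
        sources = {"reagent": ("stocks", "reagent"), "sample": ("stocks", "sample")}
        protocol = Protocol(
            name="p",
            steps=(
                ProtocolStep(0, "dispense_reagent", reagent_ref="reagent", volume=5.0),
                ProtocolStep(1, "dispense_sample", reagent_ref="sample", volume=50.0),
                ProtocolStep(2, "image", target_time_after_sample=1800),
            ),
        )
        transfers = expand_protocol(run, protocol, sources)
        assert sum(not t.is_image for t in transfers) == 4
        assert sum(t.is_image for t in transfers) == 2

    def test_96_conditions_two_liquid_steps(self):
        run = make_run(96)
        transfers = expand_protocol(run, flat_protocol(2, image_at=None), SOURCES)
        assert len(transfers) == 192

    def test_unresolvable_reagent_names_condition_and_step(self, small_run,
                                                           three_step_protocol):
        with pytest.raises(ValueError, match=r"det_D1.*step 0|step 0.*det_D1"):
            expand_protocol(small_run, three_step_protocol, sources={})

    def test_shared_mixture_prepared_before_first_use(self):
        run = make_run(8)
        stocks = [StockSolution("conj", {"c": 100.0}, 1e6)]
        recipe = plan_mixture({"c": 25.0}, stocks, 500.0, target_id="detmix")
        protocol = flat_protocol(2, image_at=600)
        transfers = expand_protocol(
            run, protocol,
            sources={"reagent": ("stocks", "reagent")},
            recipes={"detmix": recipe},
        )
        # reagent_ref "reagent" resolves to a stock, so re-point step 0 at the
        # mixture instead by templating
        protocol2 = Protocol(
            name="p",
            steps=(
                ProtocolStep(0, "dispense_reagent", reagent_ref="detmix",
                             volume=10.0, duration=10),
                ProtocolStep(1, "dispense_sample", reagent_ref="reagent",
                             volume=50.0, duration=10),
                ProtocolStep(2, "image", target_time_after_sample=600, duration=5),
            ),
        )
        transfers = expand_protocol(
            run, protocol2, sources=SOURCES, recipes={"detmix": recipe}
        )
        preps = [t for t in transfers if t.is_prep]
        strip_uses = [t for t in transfers
                      if t.source and t.source[0] == "mixtures"]
        assert len(preps) == 2  # stock transfer + diluent
        assert len(strip_uses) == 8
        wl = schedule_run(transfers, protocol2, RobotConfig())
        prep_end = max(t.scheduled_start for t in wl.rows if t.is_prep) + 10
        first_use = min(t.scheduled_start for t in wl.rows
                        if t.source and t.source[0] == "mixtures")
        assert first_use >= prep_end
        report = simulate_worklist(wl, protocol2)
        assert report.feasible, str(report)


class TestBatching:
    def identical(self, n, volume=10.0):
        return [
            Transfer(0, f"c{i}", "dispense_reagent", ("stocks", "r"),
                     ("H1", i, "w"), volume, "default", step_index=0)
            for i in range(n)
        ]

    def test_16_identical_transfers_make_2_batches(self):
        batches = batch_transfers(self.identical(16), n_channels=8)
        assert [len(b.transfers) for b in batches] == [8, 8]

    def test_mixed_volumes_never_share_a_batch(self):
        transfers = self.identical(8, 10.0) + self.identical(8, 20.0)
        batches = batch_transfers(transfers, n_channels=8)
        assert len(batches) == 2
        for b in batches:
            assert len({t.volume for t in b.transfers}) == 1

    def test_13_transfers_fill_greedily(self):
        batches = batch_transfers(self.identical(13), n_channels=8)
        assert [len(b.transfers) for b in batches] == [8, 5]

    def test_channels_assigned_within_limit(self):
        batches = batch_transfers(self.identical(13), n_channels=8)
        for b in batches:
            channels = [t.channel for t in b.transfers]
            assert channels == list(range(1, len(channels) + 1))


class TestScheduleRun:
    def test_single_strip_timing(self, three_step_protocol, small_sources):
        design = DesignSpec(factors=(FactorSpec("detection", ("D1",)),
                                     FactorSpec("matrix", ("blank",))))
        deck = DeckLayout(holders=(("H1", 16),))
        run = split_into_runs(enumerate_conditions(design), deck)[0]
        wl = build_worklist(run, three_step_protocol, sources=small_sources)
        starts = [t.scheduled_start for t in wl.rows]
        assert starts[0] == 0
        assert starts[1] >= 120
        sample = starts[1]
        image = [t for t in wl.rows if t.is_image][0].scheduled_start
        assert abs(image - (sample + 1800)) <= 60

    def test_zero_strips_gives_empty_worklist(self, three_step_protocol):
        wl = schedule_run([], three_step_protocol, RobotConfig())
        assert len(wl) == 0

    def test_24_strips_all_imaged_within_window(self):
        run = make_run(24)
        protocol = flat_protocol(2, image_at=1800, durations=30)
        wl = schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                          RobotConfig())
        report = simulate_worklist(wl, protocol)
        assert report.feasible, str(report)
        assert len(wl.imaging_events()) == 24

    def test_deterministic_output(self):
        run = make_run(20)
        protocol = flat_protocol(3, image_at=1800)
        wls = [
            schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                         RobotConfig())
            for _ in range(2)
        ]
        assert wls[0].rows == wls[1].rows

    def test_capacity_refusal(self):
        run = make_run(20, cap=96)
        deck = DeckLayout(holders=(("H1", 16),))
        protocol = flat_protocol(2, image_at=None)
        transfers = expand_protocol(run, protocol, SOURCES)
        with pytest.raises(ValueError, match="capacity"):
            schedule_run(transfers, protocol, RobotConfig(), deck=deck)

    def test_infeasible_deadline_proposes_smaller_run(self):
        # a mandatory 300 s post-sample reagent wait pushes imaging (due at
        # 60 s +/- 10 s) past its window for every strip
        protocol = Protocol(
            name="impossible",
            steps=(
                ProtocolStep(0, "dispense_sample", reagent_ref="reagent",
                             volume=50.0, duration=10),
                ProtocolStep(1, "dispense_reagent", reagent_ref="reagent",
                             volume=10.0, min_delay_after_previous=300, duration=10),
                ProtocolStep(2, "image", target_time_after_sample=60, duration=5),
            ),
            imaging_tolerance_s=10,
        )
        run = make_run(4)
        transfers = expand_protocol(run, protocol, SOURCES)
        with pytest.raises(InfeasibleSchedule) as exc:
            schedule_run(transfers, protocol, RobotConfig())
        assert exc.value.suggested_run_size >= 1

    def test_completeness_bijection(self):
        run = make_run(30)
        protocol = flat_protocol(3, image_at=2000)
        wl = schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                          RobotConfig())
        pairs = [(t.condition_id, t.step_index) for t in wl.rows]
        expected = [(c.condition_id, s.step_index)
                    for c in run.conditions for s in protocol.steps]
        assert sorted(pairs) == sorted(expected)

    def test_rows_ordered_by_start_then_batch_then_channel(self):
        run = make_run(30)
        protocol = flat_protocol(2, image_at=1800)
        wl = schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                          RobotConfig())
        keys = [(t.scheduled_start, t.batch_id, t.channel) for t in wl.rows]
        assert keys == sorted(keys)


class TestCsvDialect:
    def roundtrip(self, wl: Worklist) -> Worklist:
        buf = io.StringIO()
        write_worklist_csv(wl, buf)
        return read_worklist_csv(io.StringIO(buf.getvalue()))

    def test_roundtrip_field_for_field(self, small_run, three_step_protocol,
                                       small_sources):
        wl = build_worklist(small_run, three_step_protocol, sources=small_sources)
        back = self.roundtrip(wl)
        assert back.run_index == wl.run_index
        assert back.rows == wl.rows

    def test_written_bytes_are_stable(self, small_run, three_step_protocol,
                                      small_sources):
        texts = []
        for _ in range(2):
            wl = build_worklist(small_run, three_step_protocol,
                                sources=small_sources)
            buf = io.StringIO()
            write_worklist_csv(wl, buf)
            texts.append(buf.getvalue())
        assert texts[0] == texts[1]

    def test_imaging_rows_leave_volume_and_source_blank(self, small_run,
                                                        three_step_protocol,
                                                        small_sources):
        wl = build_worklist(small_run, three_step_protocol, sources=small_sources)
        buf = io.StringIO()
        write_worklist_csv(wl, buf)
        image_lines = [ln for ln in buf.getvalue().splitlines()[1:]
                       if ",image," in ln]
        assert image_lines
        for ln in image_lines:
            fields = ln.split(",")
            assert fields[4] == "" and fields[5] == "" and fields[9] == ""

    def test_bad_header_rejected(self):
        with pytest.raises(ValueError, match="header"):
            read_worklist_csv(io.StringIO("a,b,c\n1,2,3\n"))


class TestSimulator:
    def feasible_case(self, n=16):
        run = make_run(n)
        protocol = flat_protocol(2, image_at=900)
        wl = schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                          RobotConfig())
        return wl, protocol

    def test_scheduler_output_is_feasible(self):
        wl, protocol = self.feasible_case()
        assert simulate_worklist(wl, protocol).feasible

    def test_gantry_overlap_detected(self):
        wl, protocol = self.feasible_case()
        bad = copy.deepcopy(wl)
        # force two distinct batches to overlap in time
        b0 = bad.rows[0].batch_id
        other = next(t for t in bad.rows if t.batch_id != b0)
        for t in bad.rows:
            if t.batch_id == other.batch_id:
                t.scheduled_start = bad.rows[0].scheduled_start + 1
        report = simulate_worklist(bad, protocol)
        assert any(v.kind == "gantry_overlap" for v in report.violations)

    def test_stock_depletion_detected(self):
        run = make_run(10)
        protocol = flat_protocol(1, image_at=None, durations=10)
        transfers = expand_protocol(run, protocol, SOURCES)
        for t in transfers:
            t.volume = 50.0
        wl = schedule_run(transfers, protocol, RobotConfig())
        report = simulate_worklist(wl, protocol, stocks={"reagent": 400.0})
        assert any(v.kind == "stock_depletion" for v in report.violations)

    def test_delay_violation_detected(self):
        run = make_run(4)
        protocol = Protocol(
            name="p",
            steps=(
                ProtocolStep(0, "dispense_reagent", reagent_ref="reagent",
                             volume=5.0, duration=10),
                ProtocolStep(1, "dispense_sample", reagent_ref="reagent",
                             volume=50.0, min_delay_after_previous=120, duration=10),
            ),
        )
        wl = schedule_run(expand_protocol(run, protocol, SOURCES), protocol,
                          RobotConfig())
        bad = copy.deepcopy(wl)
        for t in bad.rows:
            if t.action == "dispense_sample":
                t.scheduled_start = 5  # before the 120 s wait has elapsed
        report = simulate_worklist(bad, protocol)
        assert any(v.kind == "delay" for v in report.violations)

    def test_imaging_deadline_violation_detected(self):
        wl, protocol = self.feasible_case(n=4)
        bad = copy.deepcopy(wl)
        for t in bad.rows:
            if t.is_image:
                t.scheduled_start += 1000
        report = simulate_worklist(bad, protocol)
        assert any(v.kind == "deadline" for v in report.violations)

    @pytest.mark.parametrize("seed", range(25))
    def test_feasibility_closure_on_random_cases(self, seed):
        """simulate(schedule(x)) is violation-free for generated feasible x."""
        run, protocol, sources, recipes, config, levels = random_schedule_case(
            seed, max_strips=48
        )
        wl = build_worklist(run, protocol, sources=sources, recipes=recipes,
                            config=config)
        report = simulate_worklist(wl, protocol, stocks=levels, config=config)
        assert report.feasible, f"seed {seed}: {report}"
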
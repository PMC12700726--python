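"""Vocal events, behavioral contexts, and the behavior-rhythm test.

Merges the night's calls into events (5-s rule), attaches every logged
behavior within 10 s before/after each event, tabulates context
categories by hour, and runs the Friedman test asking whether the
category mix varies across the night.
"""

from nocturne.events import (
    attach_context,
    context_category_table,
    merge_calls,
)
from nocturne.events import BehaviorRecord, RawCall
from nocturne.models import friedman_behavior_test
from nocturne.synth import SimulationConfig, gen_behaviors, gen_night_audio

cfg = SimulationConfig.desk_scale()
night = gen_night_audio(cfg, seed=8)
log_df = gen_behaviors(cfg, night.calls, seed=9)

calls = [RawCall(time=t.to_pydatetime()) for t in night.calls["time"]]
log = [BehaviorRecord(time=r.time.to_pydatetime(), individual_id=r.individual_id,
                      behavior=r.behavior) for r in log_df.itertuples()]

events = merge_calls(calls, gap_s=5.0)
contexts = attach_context(events, log, window_s=10.0)
table = context_category_table(contexts)

print(f"{len(calls)} calls -> {len(events)} events, "
      f"{sum(len(c.pre) + len(c.post) for c in contexts)} context behaviors\n")
print(table.to_string())
stat, df, p = friedman_behavior_test(table)
print(f"\nFriedman test (blocks = hours, treatments = aggression/social/other):")
print(f"chi-square = {stat:.2f}, df = {df}, p = {p:.4f}")
print("The test detects *consistent* level differences between categories")
print("across hours. Here aggression dominates early and social dominates")
print("late, so their mean ranks balance and the test can stay non-significant")
print("even though the hourly mix clearly shifts (see the table).")
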
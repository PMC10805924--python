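"""Build the trial schedules and a concrete search display.

A session interleaves plateau phases (all 14 distractors share one shape)
with 13-trial transitions that flip the shape ratio one distractor at a
time.  The printed counts show the cycle structure; the display realises
one trial as 16 items on the 5 x 7 grid.
"""

from acvs import build_cycle, build_session, render_display

cycle = build_cycle("star")
print("one cycle:", len(cycle), "trials")
print(cycle[["phase", "n_star_distractors", "n_pentagon_distractors"]]
      .iloc[[0, 1, 2, 3, 9, 15, 16, 17, 18, 19]].to_string(index=False))

online = build_session(2, 4)    # two practice + four main blocks
lab = build_session(2, 8)
print(f"\nonline-scale session: {len(online)} trials "
      f"({online.groupby('block').size().tolist()})")
print(f"lab-scale session:    {len(lab)} trials")

display = render_display(online.iloc[0], rng=0)
print("\nexample display (first trial, star plateau):")
print(display[["item", "row", "col", "role", "shape", "digit"]].head(6)
      .to_string(index=False))
print("...")
print("composition:", display["role"].value_counts().to_dict(),
      display["shape"].value_counts().to_dict())
print("\nThe two blue targets always carry distinct digits 1-4; the unique-"
      "shaped target is the one sharing a shape with zero distractors.")
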
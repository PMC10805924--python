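"""Trial schedules and search displays for the adaptive-choice visual search task.

The paradigm presents 16 items per trial: two blue targets (one star, one
pentagon) among 14 black distractors whose shape composition changes over a
fixed "cycle": a 3-trial plateau in which every distractor shares one shape,
a 13-trial transition in which one distractor per trial switches to the other
shape, the opposite plateau, and a transition back.  Blocks concatenate
cycles and append a final plateau; whether a block opens with a star or a
pentagon plateau alternates between consecutive blocks.

Schedules are plain :class:`pandas.DataFrame` objects with the columns listed
in :data:`SCHEDULE_COLUMNS`; displays use :data:`DISPLAY_COLUMNS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STAR = "star"
PENTAGON = "pentagon"
SHAPES = (STAR, PENTAGON)

#: total distractors per display in the published design
N_DISTRACTORS = 14
#: grid geometry ("imaginary 5 x 7 grid")
GRID_ROWS, GRID_COLS = 5, 7
#: default canvas, pixels (origin top-left); only relative positions matter
CANVAS_PX = (1920, 1080)

#: angle labels (degrees on the circular shape space) for the four variants
#: of each shape class; stars sit around one pole, pentagons around the other
STAR_VARIANTS = (342, 354, 6, 18)
PENTAGON_VARIANTS = (162, 174, 186, 198)

TARGET_DIGITS = (1, 2, 3, 4)
DISTRACTOR_DIGITS = (5, 6, 7, 8)

SCHEDULE_COLUMNS = [
    "block", "block_type", "block_first_plateau", "trial", "trial_in_block",
    "cycle_index", "pos_in_cycle", "cycle_start", "phase", "phase_type",
    "plateau_state", "n_star_distractors", "n_pentagon_distractors",
]

DISPLAY_COLUMNS = [
    "item", "row", "col", "role", "shape", "variant", "color", "digit",
    "x_px", "y_px",
]


class ScheduleConfigError(ValueError):
    """Raised when schedule parameters cannot produce a valid cycle."""


def build_cycle(starting_plateau: str, plateau_len: int = 3,
                transition_len: int = 13,
                n_distractors: int = N_DISTRACTORS) -> pd.DataFrame:
    """Build one full cycle: plateau, transition, opposite plateau, transition.

    Parameters
    ----------
    starting_plateau
        ``"star"`` or ``"pentagon"``: the shape shared by *all* distractors
        on the opening plateau.
    plateau_len, transition_len, n_distractors
        Phase lengths and the fixed distractor total.  With the published
        defaults (3, 13, 14) the transition raises the minority-shape count
        by exactly one per trial.

    Returns
    -------
    pandas.DataFrame
        ``2 * (plateau_len + transition_len)`` rows with columns ``phase``,
        ``phase_type``, ``plateau_state``, ``n_star_distractors``,
        ``n_pentagon_distractors`` and ``pos_in_cycle``.
    """
    if starting_plateau not in SHAPES:
        raise ScheduleConfigError(f"unknown plateau shape {starting_plateau!r}")
    if plateau_len < 1 or transition_len < 1:
        raise ScheduleConfigError("plateau_len and transition_len must be >= 1")
    if n_distractors < transition_len:
        raise ScheduleConfigError(
            "n_distractors must be at least transition_len")

    other = PENTAGON if starting_plateau == STAR else STAR
    # count of the *other* (initially absent) shape over the cycle
    ramp = [round(k * n_distractors / (transition_len + 1))
            for k in range(1, transition_len + 1)]
    counts = ([0] * plateau_len + ramp + [n_distractors] * plateau_len
              + ramp[::-1])
    phases = ([f"P{i + 1}" for i in range(plateau_len)]
              + [f"T{i + 1}" for i in range(transition_len)]) * 2
    plateau_state = ([starting_plateau] * plateau_len
                     + [""] * transition_len
                     + [other] * plateau_len
                     + [""] * transition_len)

    n_other = np.asarray(counts)
    n_start = n_distractors - n_other
    df = pd.DataFrame({
        "pos_in_cycle": np.arange(1, len(counts) + 1),
        "phase": phases,
        "phase_type": ["plateau" if p.startswith("P") else "transition"
                       for p in phases],
        "plateau_state": plateau_state,
        "n_star_distractors": n_start if starting_plateau == STAR else n_other,
        "n_pentagon_distractors": n_other if starting_plateau == STAR else n_start,
    })
    df.attrs["starting_plateau"] = starting_plateau
    return df


def _final_plateau(state: str, plateau_len: int,
                   n_distractors: int) -> pd.DataFrame:
    n_star = n_distractors if state == STAR else 0
    return pd.DataFrame({
        "pos_in_cycle": np.arange(1, plateau_len + 1),
        "phase": [f"P{i + 1}" for i in range(plateau_len)],
        "phase_type": "plateau",
        "plateau_state": state,
        "n_star_distractors": n_star,
        "n_pentagon_distractors": n_distractors - n_star,
    })


def build_block(first_plateau: str, n_cycles: int, plateau_len: int = 3,
                transition_len: int = 13,
                n_distractors: int = N_DISTRACTORS) -> pd.DataFrame:
    """One block: ``n_cycles`` cycles plus a closing plateau of the same state.

    Each cycle ends transitioning back toward its opening plateau, so every
    cycle in the block (and the final plateau) shares ``first_plateau``.
    """
    parts = [build_cycle(first_plateau, plateau_len, transition_len,
                         n_distractors) for _ in range(n_cycles)]
    for i, part in enumerate(parts):
        part["cycle_index"] = i + 1
    tail = _final_plateau(first_plateau, plateau_len, n_distractors)
    tail["cycle_index"] = n_cycles + 1
    parts.append(tail)
    block = pd.concat(parts, ignore_index=True)
    block["cycle_start"] = first_plateau
    block["trial_in_block"] = np.arange(1, len(block) + 1)
    return block


def build_session(n_practice: int, n_main: int, cycles_per_practice: int = 1,
                  cycles_per_main: int = 3, first_block_start: str = STAR,
                  plateau_len: int = 3, transition_len: int = 13,
                  n_distractors: int = N_DISTRACTORS) -> pd.DataFrame:
    """Build a full session of practice blocks followed by main blocks.

    The opening plateau alternates between consecutive blocks, continuing
    across the practice/main boundary.  With the published defaults a
    practice block has 35 trials (one cycle + final plateau) and a main
    block 99 (three cycles + final plateau); two practice + four main blocks
    give the 466-trial session, two + eight the 862-trial session.
    """
    if n_practice < 0 or n_main < 0:
        raise ScheduleConfigError("block counts must be non-negative")
    blocks = []
    start = first_block_start
    specs = ([("practice", cycles_per_practice)] * n_practice
             + [("main", cycles_per_main)] * n_main)
    for i, (btype, n_cycles) in enumerate(specs):
        blk = build_block(start, n_cycles, plateau_len, transition_len,
                          n_distractors)
        blk["block"] = i + 1
        blk["block_type"] = btype
        blk["block_first_plateau"] = start
        blocks.append(blk)
        start = PENTAGON if start == STAR else STAR
    if not blocks:
        return pd.DataFrame(columns=SCHEDULE_COLUMNS)
    session = pd.concat(blocks, ignore_index=True)
    session["trial"] = np.arange(1, len(session) + 1)
    return session[SCHEDULE_COLUMNS]


def grid_pixel_centers(canvas_px: tuple[int, int] = CANVAS_PX) -> np.ndarray:
    """Pixel centers of the 5 x 7 grid cells, shape (rows, cols, 2)."""
    width, height = canvas_px
    xs = (np.arange(GRID_COLS) + 0.5) * width / GRID_COLS
    ys = (np.arange(GRID_ROWS) + 0.5) * height / GRID_ROWS
    centers = np.empty((GRID_ROWS, GRID_COLS, 2))
    centers[..., 0] = xs[None, :]
    centers[..., 1] = ys[:, None]
    return centers


def render_display(schedule_trial, rng,
                   canvas_px: tuple[int, int] = CANVAS_PX) -> pd.DataFrame:
    """Realise one schedule trial as a concrete 16-item search display.

    Items are placed on distinct cells of the 5 x 7 grid chosen uniformly at
    random; shape variants are drawn uniformly from the four per class; the
    two blue targets carry distinct digits from 1-4 and the black distractors
    random digits from 5-8.  Deterministic given the random state.

    Parameters
    ----------
    schedule_trial
        One row of a schedule frame (anything with ``n_star_distractors``
        and ``n_pentagon_distractors`` entries).
    rng
        :class:`numpy.random.Generator` or an integer seed.
    """
    rng = np.random.default_rng(rng)
    n_star = int(schedule_trial["n_star_distractors"])
    n_pent = int(schedule_trial["n_pentagon_distractors"])
    n_items = n_star + n_pent + 2

    cells = rng.choice(GRID_ROWS * GRID_COLS, size=n_items, replace=False)
    rows, cols = np.divmod(cells, GRID_COLS)
    centers = grid_pixel_centers(canvas_px)

    shapes = ([STAR, PENTAGON] + [STAR] * n_star + [PENTAGON] * n_pent)
    roles = ["target", "target"] + ["distractor"] * (n_items - 2)
    target_digits = rng.choice(TARGET_DIGITS, size=2, replace=False)
    digits = np.concatenate([target_digits,
                             rng.choice(DISTRACTOR_DIGITS, size=n_items - 2)])
    variants = [int(rng.choice(STAR_VARIANTS if s == STAR
                               else PENTAGON_VARIANTS)) for s in shapes]

    df = pd.DataFrame({
        "item": np.arange(n_items),
        "row": rows,
        "col": cols,
        "role": roles,
        "shape": shapes,
        "variant": variants,
        "color": ["blue", "blue"] + ["black"] * (n_items - 2),
        "digit": digits.astype(int),
        "x_px": centers[rows, cols, 0],
        "y_px": centers[rows, cols, 1],
    })
    return df[DISPLAY_COLUMNS]


def validate_schedule(schedule: pd.DataFrame,
                      n_distractors: int = N_DISTRACTORS) -> None:
    """Raise ``ValueError`` if a schedule violates its structural invariants."""
    total = schedule["n_star_distractors"] + schedule["n_pentagon_distractors"]
    if not (total == n_distractors).all():
        raise ValueError("distractor counts do not sum to the fixed total")
    plateaus = schedule[schedule["phase_type"] == "plateau"]
    minority = plateaus[["n_star_distractors", "n_pentagon_distractors"]].min(axis=1)
    if not (minority == 0).all():
        raise ValueError("plateau trial with distractors of both shapes")
    if "block_first_plateau" in schedule:
        firsts = schedule.drop_duplicates("block")["block_first_plateau"]
        if (firsts.values[1:] == firsts.values[:-1]).any():
            raise ValueError("consecutive blocks share their first plateau")
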
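"""Synthetic worm lifespan + position-log experiment.

Mortality follows a Weibull law (heavy right tail, scalable median):
event time T = lambda * W with W ~ Weibull(shape) and lambda chosen so
the arm's median is multiplier * median_control_lifespan.  Worms are
spread over plates; each worm performs a lazy random walk on the plate
arena: at a frame at time t it jumps to a nearby pixel with probability
2^(-t / (activity_halflife * multiplier)) and otherwise stays put.
Dead worms freeze at their last position but remain visible to the
scanner, as on the real platform.  Scaling the activity half-life by
the arm's lifespan multiplier ties healthspan to lifespan, so
longer-lived arms stay active proportionally longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WormExperimentConfig:
    n_worms_per_arm: int = 500
    arms: dict[str, float] = field(default_factory=lambda: {"control": 1.0, "treated": 1.25})
    shape: float = 4.0
    median_control_lifespan: float = 20.0
    censor_prob: float = 0.0
    arena: tuple[int, int] = (120, 120)
    frames_per_day: int = 2
    activity_halflife: float = 4.0
    worms_per_plate: int = 30
    jump_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms_per_arm < 1:
            raise ValueError("n_worms_per_arm must be >= 1")
        if any(m <= 0 for m in self.arms.values()):
            raise ValueError("arm lifespan multipliers must be positive")
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must be in [0, 1]")
        if self.shape <= 0 or self.median_control_lifespan <= 0:
            raise ValueError("shape and median_control_lifespan must be positive")
        if self.activity_halflife <= 0:
            raise ValueError("activity_halflife must be positive")


def generate_worm_experiment(
    config: WormExperimentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (survival table, position log).

    Survival columns: worm, arm, day, censored, plate.  Position-log
    columns: plate, timepoint (days), x, y — one row per tracked worm
    object per frame, in the `animal_position.csv` dialect.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.arena

    surv_rows = []
    worm_states = []  # (plate, arm, death_day, stop_day)
    for arm, mult in config.arms.items():
        median = config.median_control_lifespan * mult
        lam = median / np.log(2.0) ** (1.0 / config.shape)
        times = lam * rng.weibull(config.shape, size=config.n_worms_per_arm)
        times = np.maximum(times, 0.01)
        censored = rng.random(config.n_worms_per_arm) < config.censor_prob
        obs = times.copy()
        obs[censored] = rng.uniform(0.0, times[censored])
        obs = np.maximum(obs, 0.01)
        for i in range(config.n_worms_per_arm):
            plate = f"{arm}-p{i // config.worms_per_plate:02d}"
            surv_rows.append(
                {
                    "worm": f"{arm}-w{i:04d}",
                    "arm": arm,
                    "day": round(float(obs[i]), 2),
                    "censored": int(censored[i]),
                    "plate": plate,
                }
            )
            # censored worms vanish from the plate at their censor day;
            # dead worms freeze but stay visible
            death = float(times[i]) if not censored[i] else np.inf
            stop = float(obs[i]) if censored[i] else np.inf
            worm_states.append((plate, mult, death, stop))

    survival = pd.DataFrame(surv_rows)

    max_day = float(survival["day"].max())
    n_frames = int(np.ceil(max_day * config.frames_per_day)) + 1
    frame_times = np.arange(1, n_frames + 1) / config.frames_per_day

    n_worms = len(worm_states)
    x = rng.integers(0, w, size=n_worms).astype(np.int64)
    y = rng.integers(0, h, size=n_worms).astype(np.int64)
    plates = np.array([s[0] for s in worm_states])
    mults = np.array([s[1] for s in worm_states])
    deaths = np.array([s[2] for s in worm_states])
    stops = np.array([s[3] for s in worm_states])

    recs: list[pd.DataFrame] = []
    for t in frame_times:
        alive = t <= deaths
        present = t <= stops
        p_move = np.exp2(-t / (config.activity_halflife * mults))
        moving = alive & (rng.random(n_worms) < p_move)
        dx = rng.integers(-config.jump_size, config.jump_size + 1, size=n_worms)
        dy = rng.integers(-config.jump_size, config.jump_size + 1, size=n_worms)
        x = np.where(moving, np.clip(x + dx, 0, w - 1), x)
        y = np.where(moving, np.clip(y + dy, 0, h - 1), y)
        recs.append(
            pd.DataFrame(
                {
                    "plate": plates[present],
                    "timepoint": np.full(int(present.sum()), float(t)),
                    "x": x[present],
                    "y": y[present],
                }
            )
        )
    positions = pd.concat(recs, ignore_index=True)
    return survival, positions
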
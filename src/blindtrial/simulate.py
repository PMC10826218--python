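"""Synthetic two-arm blinding trials.

Generates complete respondent-level datasets with the structure the analysis
assumes: 1:1 allocation by stratified permuted-block randomisation (blocks of
sizes 2 and 4 by default, stratified by a binary covariate such as prior
manual-therapy experience), five-category guess behaviour for the participant
and each of three outcome assessors, and normally distributed range-of-motion
outcomes (post = pre + change, both Gaussian).

Guess behaviour per role is a multinomial over {correct direction, incorrect
direction, don't know} with probabilities (theta_correct, theta_incorrect,
theta_dontknow); directed guesses are split into "strongly"/"somewhat" by an
independent ``strong_fraction`` coin. Under this model the arm-level Bang
index estimates theta_correct - theta_incorrect. Default parameters mirror
the observed response proportions of the 24-person study this package
reconstructs (participants guessed correctly about 46% of the time; one
assessor never guessed; the others split roughly evenly), with ROM location
and spread taken from its published summary tables. All randomness flows
through one seeded generator, so a config plus seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .blinding import ARMS, GuessCategory
from .reconstruction import ROLES, ROM_COLUMNS

__all__ = [
    "GuessBehavior",
    "RomParams",
    "RomModel",
    "ScenarioConfig",
    "permuted_block_randomize",
    "simulate_guesses",
    "simulate_rom",
    "simulate_trial",
]


class GuessBehavior(BaseModel):
    """Multinomial response behaviour of one respondent role."""

    theta_correct: float = Field(ge=0, le=1)
    theta_incorrect: float = Field(ge=0, le=1)
    theta_dontknow: float = Field(ge=0, le=1)
    strong_fraction: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _theta_sums_to_one(self) -> "GuessBehavior":
        total = self.theta_correct + self.theta_incorrect + self.theta_dontknow
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"theta triple must sum to 1, got {total}")
        return self

    @property
    def thetas(self) -> tuple[float, float, float]:
        return (self.theta_correct, self.theta_incorrect, self.theta_dontknow)


class RomParams(BaseModel):
    """Gaussian pre-intervention level and additive change, in degrees."""

    pre_mean: float
    pre_sd: float = Field(ge=0)
    change_mean: float
    change_sd: float = Field(ge=0)


class RomModel(BaseModel):
    """Per-arm flexion and extension models."""

    flexion: dict[str, RomParams]
    extension: dict[str, RomParams]

    @field_validator("flexion", "extension")
    @classmethod
    def _arms_present(cls, v: dict[str, RomParams]) -> dict[str, RomParams]:
        if set(v) != set(ARMS):
            raise ValueError(f"need parameters for arms {ARMS}")
        return v


def _default_guess_behaviour() -> dict[str, GuessBehavior]:
    # observed pooled response proportions of the reconstructed study
    return {
        "participant": GuessBehavior(theta_correct=11 / 24, theta_incorrect=4 / 24,
                                     theta_dontknow=9 / 24),
        "assessor_1": GuessBehavior(theta_correct=0.0, theta_incorrect=0.0,
                                    theta_dontknow=1.0),
        "assessor_2": GuessBehavior(theta_correct=5 / 24, theta_incorrect=5 / 24,
                                    theta_dontknow=14 / 24),
        "assessor_3": GuessBehavior(theta_correct=8 / 24, theta_incorrect=9 / 24,
                                    theta_dontknow=7 / 24),
    }


def _default_rom_model() -> RomModel:
    # locations from the study's baseline medians, spread and change from its
    # published post-intervention and change-score summaries (degrees)
    return RomModel(
        flexion={
            "active": RomParams(pre_mean=127.0, pre_sd=18.7, change_mean=3.5, change_sd=7.9),
            "control": RomParams(pre_mean=132.0, pre_sd=11.5, change_mean=3.7, change_sd=4.3),
        },
        extension={
            "active": RomParams(pre_mean=43.0, pre_sd=13.6, change_mean=2.0, change_sd=5.7),
            "control": RomParams(pre_mean=44.0, pre_sd=15.2, change_mean=1.5, change_sd=5.3),
        },
    )


class ScenarioConfig(BaseModel):
    """Full parameterisation of a simulated trial."""

    n_participants: int = Field(default=24, ge=0)
    stratum_prevalence: float = Field(default=7 / 24, ge=0, le=1)
    block_sizes: tuple[int, ...] = (2, 4)
    guess_behaviour: dict[str, GuessBehavior] = Field(default_factory=_default_guess_behaviour)
    rom: RomModel = Field(default_factory=_default_rom_model)
    seed: int | None = None

    @field_validator("block_sizes")
    @classmethod
    def _even_blocks(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if not v:
            raise ValueError("block_sizes must be non-empty")
        for b in v:
            if b < 2 or b % 2 != 0:
                raise ValueError(f"block sizes must be even integers >= 2, got {b}")
        return v

    @field_validator("guess_behaviour")
    @classmethod
    def _known_roles(cls, v: dict[str, GuessBehavior]) -> dict[str, GuessBehavior]:
        unknown = set(v) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")
        missing = set(ROLES) - set(v)
        if missing:
            raise ValueError(f"missing behaviour for roles: {sorted(missing)}")
        return v

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls.model_validate_json(text)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def permuted_block_randomize(strata: Sequence, block_sizes: Sequence[int] = (2, 4),
                             seed: int | np.random.Generator | None = None) -> np.ndarray:
    """1:1 arm assignments by permuted blocks within each stratum.

    Block sizes are drawn uniformly at random per stratum; every block is
    balanced, so the running arm imbalance within a stratum never exceeds
    half the largest block size.
    """
    strata = np.asarray(strata)
    if strata.size == 0:
        raise ValueError("need at least one id to randomise")
    for b in block_sizes:
        if b < 2 or b % 2 != 0:
            raise ValueError(f"block sizes must be even integers >= 2, got {b}")
    rng = _as_rng(seed)
    assignments = np.empty(strata.size, dtype=object)
    for stratum in pd.unique(strata):
        idx = np.flatnonzero(strata == stratum)
        seq: list[str] = []
        while len(seq) < idx.size:
            b = int(rng.choice(block_sizes))
            block = np.array(["active", "control"] * (b // 2), dtype=object)
            rng.shuffle(block)
            seq.extend(block)
        assignments[idx] = seq[: idx.size]
    return assignments.astype(str)


def simulate_guesses(arm: str, behaviour: GuessBehavior, n: int,
                     seed: int | np.random.Generator | None = None) -> list[GuessCategory]:
    """Draw n five-category guesses for respondents whose true arm is ``arm``."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    rng = _as_rng(seed)
    other = "control" if arm == "active" else "active"
    cats = {
        ("active", "strong"): GuessCategory.STRONGLY_ACTIVE,
        ("active", "somewhat"): GuessCategory.SOMEWHAT_ACTIVE,
        ("control", "strong"): GuessCategory.STRONGLY_CONTROL,
        ("control", "somewhat"): GuessCategory.SOMEWHAT_CONTROL,
    }
    outcome = rng.choice(3, size=n, p=behaviour.thetas)  # 0 correct, 1 incorrect, 2 dk
    strong = rng.random(n) < behaviour.strong_fraction
    out: list[GuessCategory] = []
    for o, s in zip(outcome, strong):
        if o == 2:
            out.append(GuessCategory.DONT_KNOW)
        else:
            direction = arm if o == 0 else other
            out.append(cats[(direction, "strong" if s else "somewhat")])
    return out


def simulate_rom(arm: str, rom: RomModel, n: int,
                 seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Pre/post flexion and extension ROM draws (degrees): post = pre + change."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    rng = _as_rng(seed)
    data: dict[str, np.ndarray] = {}
    for movement in ("flexion", "extension"):
        params = getattr(rom, movement)[arm]
        pre = rng.normal(params.pre_mean, params.pre_sd, size=n)
        change = rng.normal(params.change_mean, params.change_sd, size=n)
        data[f"rom_pre_{movement}"] = pre
        data[f"rom_post_{movement}"] = pre + change
    return pd.DataFrame(data)


def simulate_trial(config: ScenarioConfig,
                   seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a complete trial in the respondent-level CSV schema.

    One row per participant-role pair; the participant's arm and ROM values
    are constant across their rows. ``seed`` overrides ``config.seed``.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_participants
    columns = ["participant_id", "role", "arm", "stratum", "response", *ROM_COLUMNS]
    if n == 0:
        return pd.DataFrame(columns=columns)
    strata = (rng.random(n) < config.stratum_prevalence).astype(int)
    arms = permuted_block_randomize(strata, config.block_sizes, rng)
    ids = [f"P{i + 1:02d}" for i in range(n)]

    rom_parts = []
    for arm in ARMS:
        mask = arms == arm
        part = simulate_rom(arm, config.rom, int(mask.sum()), rng)
        part.index = np.flatnonzero(mask)
        rom_parts.append(part)
    rom_df = pd.concat(rom_parts).sort_index()

    rows = []
    for role in ROLES:
        behaviour = config.guess_behaviour[role]
        guesses = np.empty(n, dtype=object)
        for arm in ARMS:
            mask = arms == arm
            guesses[mask] = simulate_guesses(arm, behaviour, int(mask.sum()), rng)
        for i in range(n):
            rows.append({
                "participant_id": ids[i],
                "role": role,
                "arm": arms[i],
                "stratum": int(strata[i]),
                "response": guesses[i].value,
                **{col: float(rom_df.iloc[i][col]) for col in ROM_COLUMNS},
            })
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["participant_id", "role"], kind="stable").reset_index(drop=True)
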
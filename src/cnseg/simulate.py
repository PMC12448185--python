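"""Seeded synthetic cohorts with known ground truth.

Profiles start from a sex-aware diploid baseline, receive class-specific
events (arm-level gains/losses, focal amplifications, LoH tracts), optional
whole-genome doubling and per-segment CN jitter, and are finally punched
with missing-data gaps. Everything that was planted is recorded in the
returned truth table, so downstream recovery (peaks, outliers, filters) can
be verified against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import Allele, ReferenceGenome, Region, Sex, normal_copy
from .impute import merge_equal_neighbors
from .profile import ALLELE_SPECIFIC, CNProfile

__all__ = ["ClassTemplate", "Event", "SimConfig", "SimTruth", "simulate_cohort"]

EVENT_KINDS = ("gain", "loss", "focal_amp", "loh")


@dataclass(frozen=True)
class Event:
    """One planted alteration applied to every sample of a class.

    ``gain``/``loss`` shift the major allele by ``amplitude`` (typically
    arm-scale), ``focal_amp`` does the same for narrow regions, and ``loh``
    sets the minor allele to 0.
    """

    kind: str
    chrom: str
    start: int
    end: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid event interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ClassTemplate:
    name: str
    events: Tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class SimConfig:
    genome: ReferenceGenome
    n_samples: int = 10
    classes: Tuple[ClassTemplate, ...] = (ClassTemplate("baseline"),)
    gap_fraction: float = 0.0
    gap_placement: str = "centromere"  # or "uniform"
    wgd_probability: float = 0.0
    noise: float = 0.0
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        for frac in (self.gap_fraction, self.wgd_probability, self.male_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.gap_placement not in ("centromere", "uniform"):
            raise ValueError(f"unknown gap placement {self.gap_placement!r}")
        for cls in self.classes:
            for ev in cls.events:
                if ev.chrom not in self.genome:
                    raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
                if ev.end > self.genome.length_of(ev.chrom):
                    raise ValueError(f"event {ev} exceeds chromosome bounds")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    samples: pd.DataFrame  # sample_id, class, sex, wgd
    events: Dict[str, Tuple[Event, ...]]  # class name -> planted events
    complete_profiles: Dict[str, CNProfile]  # pre-gap (true per-base CN)


# ---------------------------------------------------------------------------


def _split_pieces(pieces: List[List], start: int, end: int) -> None:
    """Split interval pieces [s, e, maj, min] in place at start and end."""
    for cut in (start, end):
        for i, (s, e, ma, mi) in enumerate(pieces):
            if s < cut < e:
                pieces[i] = [s, cut, ma, mi]
                pieces.insert(i + 1, [cut, e, ma, mi])
                break


def _apply_event(pieces: List[List], ev: Event) -> None:
    _split_pieces(pieces, ev.start, ev.end)
    for piece in pieces:
        if piece[0] >= ev.start and piece[1] <= ev.end:
            if ev.kind == "loh":
                piece[3] = 0.0
            elif ev.kind == "loss":
                piece[2] = max(piece[2] - ev.amplitude, 0.0)
            else:  # gain / focal_amp
                piece[2] = piece[2] + ev.amplitude


def _punch_gap(pieces: List[List], start: int, end: int) -> List[List]:
    _split_pieces(pieces, start, end)
    return [p for p in pieces if not (p[0] >= start and p[1] <= end)]


def simulate_cohort(
    config: SimConfig, seed: Optional[int] = None
) -> Tuple[Dict[str, CNProfile], SimTruth]:
    """Generate ``n_samples`` profiles per class; fully seed-deterministic."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome = config.genome
    cohort: Dict[str, CNProfile] = {}
    complete: Dict[str, CNProfile] = {}
    rows = []

    for cls in config.classes:
        for i in range(config.n_samples):
            sample_id = f"{cls.name}_{i:03d}"
            sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
            wgd = bool(rng.random() < config.wgd_probability)

            by_chrom: Dict[str, List[List]] = {}
            for chrom, length in genome.chromosomes:
                maj = float(normal_copy(chrom, Allele.MAJOR, sex, genome))
                mi = float(normal_copy(chrom, Allele.MINOR, sex, genome))
                by_chrom[chrom] = [[0, length, maj, mi]]
            for ev in cls.events:
                _apply_event(by_chrom[ev.chrom], ev)
            if wgd:
                for pieces in by_chrom.values():
                    for p in pieces:
                        p[2] *= 2.0
                        p[3] *= 2.0
            if config.noise > 0:
                for pieces in by_chrom.values():
                    for p in pieces:
                        p[2] = max(p[2] + rng.normal(0.0, config.noise), 0.0)
                        p[3] = max(p[3] + rng.normal(0.0, config.noise), 0.0)

            def _to_profile(chrom_map: Dict[str, List[List]]) -> CNProfile:
                recs = [
                    {"chrom": c, "start": s, "end": e, "cn_major": ma, "cn_minor": mi}
                    for c, pieces in chrom_map.items()
                    for s, e, ma, mi in pieces
                ]
                prof = CNProfile(
                    sample_id,
                    pd.DataFrame(recs),
                    ALLELE_SPECIFIC,
                    genome,
                    declared_sex=sex,
                )
                return merge_equal_neighbors(prof)

            complete[sample_id] = _to_profile(by_chrom)

            if config.gap_fraction > 0:
                for chrom, length in genome.chromosomes:
                    gap_len = int(round(config.gap_fraction * length))
                    if gap_len <= 0:
                        continue
                    gap_len = min(gap_len, length - 1)
                    if config.gap_placement == "centromere":
                        # centered on the chromosome midpoint with small jitter
                        mid = length // 2 + int(
                            rng.integers(-length // 20, length // 20 + 1)
                        )
                        start = int(np.clip(mid - gap_len // 2, 0, length - gap_len))
                    else:
                        start = int(rng.integers(0, length - gap_len + 1))
                    by_chrom[chrom] = _punch_gap(
                        by_chrom[chrom], start, start + gap_len
                    )
            cohort[sample_id] = _to_profile(by_chrom)
            rows.append(
                {
                    "sample_id": sample_id,
                    "class": cls.name,
                    "sex": sex.value,
                    "wgd": wgd,
                }
            )

    truth = SimTruth(
        samples=pd.DataFrame(rows),
        events={cls.name: cls.events for cls in config.classes},
        complete_profiles=complete,
    )
    return cohort, truth


def config_from_dict(data: dict, genome: ReferenceGenome) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping (for the CLI)."""
    known = {
        "n_samples",
        "classes",
        "gap_fraction",
        "gap_placement",
        "wgd_probability",
        "noise",
        "male_fraction",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    classes = []
    for cls in data.get("classes", [{"name": "baseline"}]):
        events = tuple(
            Event(
                kind=ev["kind"],
                chrom=ev["chrom"],
                start=int(ev["start"]),
                end=int(ev["end"]),
                amplitude=float(ev.get("amplitude", 1.0)),
            )
            for ev in cls.get("events", [])
        )
        classes.append(ClassTemplate(cls["name"], events))
    kwargs = {k: v for k, v in data.items() if k in known and k != "classes"}
    return SimConfig(genome=genome, classes=tuple(classes), **kwargs)
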
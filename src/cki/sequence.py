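"""Acquisition schedule for the CKI ³¹P-MRF sequence.

The sequence plays 800 frequency-selective excitations organised in four
sinusoidal flip-angle blocks of 200 pulses each.  Blocks 1 and 3 excite
phosphocreatine (PCr, amplitude 35°), blocks 2 and 4 the γ-phosphate of ATP
(amplitude 25°); RF phase alternates 0°/180° as in a balanced SSFP train.
Each block is preceded by an adiabatic-style asymmetric inversion
preparation (40 ms), a 2 ms delay and an 8 ms crusher, and followed by a
400 ms relaxation pause.  Every second PCr excitation carries an extra
echo-shift delay Te+ = 4 ms that encodes ΔB0 in the signal phase.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "PulseSpec",
    "SequenceConfig",
    "ScheduleEvent",
    "AcquisitionSchedule",
    "build_fa_pattern",
    "build_schedule",
]

N_PER_BLOCK = 200
N_BLOCKS = 4
N_EXCITATIONS = N_PER_BLOCK * N_BLOCKS


@dataclass(frozen=True)
class PulseSpec:
    """One RF or gradient event.

    ``carrier_offset`` is in ppm relative to PCr; ``shape`` identifies the
    envelope: a truncated Gaussian for excitation (``fwhm`` in Hz) or an
    asymmetric inversion profile for the preparation pulses.
    """

    kind: Literal["excitation", "inversion", "crusher", "delay", "readout"]
    duration: float
    nominal_flip: float = 0.0
    rf_phase: float = 0.0
    carrier_offset: float = 0.0
    shape: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError(f"pulse duration must be positive, got {self.duration}")
        if self.kind == "excitation" and not 0.0 <= self.nominal_flip <= 180.0:
            raise ValueError(f"flip angle out of [0, 180]: {self.nominal_flip}")


# (eps_pcr, eps_atp) per preparation pulse.  The default follows from the
# pulse carriers and the mirrored profiles: prep 1 (+1.25 ppm, inverted side
# below the transition) inverts BOTH pools; preps 2 and 4 (−1.25 ppm,
# opposite orientation) invert only PCr, whose inversion recovery then runs
# undisturbed through the ATP readout blocks (IR for T1 sensitivity on PCr
# only); prep 3 (−1.25 ppm, same orientation as prep 1) inverts only γATP,
# so the following PCr block reads the inversion transfer through the CK
# exchange.  The assignment is configurable because it is a modelling
# choice, not a directly printed quantity.
_DEFAULT_PREP_EFFICIENCIES = ((-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (-1.0, 1.0))


@dataclass(frozen=True)
class SequenceConfig:
    """Timing and RF constants of one FA-pattern repetition.

    All durations in seconds, flips in degrees, carriers in ppm vs PCr.
    """

    a_pcr: float = 35.0
    a_atp: float = 25.0
    n_per_block: int = N_PER_BLOCK
    tr1: float = 19.82e-3
    te: float = 410e-6
    te_plus: float = 4e-3
    pulse_duration: float = 10e-3
    pulse_fwhm_hz: float = 170.0
    inv_duration: float = 40e-3
    post_inv_delay: float = 2e-3
    crusher_duration: float = 8e-3
    block_pause: float = 0.4
    readout_duration: float = 8.61e-3
    refocus_delay: float = 920e-6
    pcr_ppm: float = 0.0
    atp_ppm: float = -2.52
    prep_carriers_ppm: tuple = (1.25, -1.25, -1.25, -1.25)
    prep_efficiencies: tuple = _DEFAULT_PREP_EFFICIENCIES
    # inorganic phosphate (+4.9 ppm) lies ~590 Hz from every prep carrier,
    # far outside the narrow band of a 40 ms inversion pulse, so the preps
    # leave Pi untouched by default; only used by three-pool models
    prep_pi_efficiencies: tuple = (1.0, 1.0, 1.0, 1.0)
    prep_timing: Literal["start", "mid", "end"] = "mid"

    @property
    def tr2(self) -> float:
        return self.tr1 + self.te_plus

    def validate(self) -> None:
        for name in (
            "tr1",
            "te",
            "te_plus",
            "pulse_duration",
            "inv_duration",
            "post_inv_delay",
            "crusher_duration",
            "block_pause",
            "readout_duration",
            "refocus_delay",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite duration, got {v}")
        if self.n_per_block < 1:
            raise ValueError("n_per_block must be >= 1")
        if (
            len(self.prep_carriers_ppm) != N_BLOCKS
            or len(self.prep_efficiencies) != N_BLOCKS
            or len(self.prep_pi_efficiencies) != N_BLOCKS
        ):
            raise ValueError("prep settings must list one entry per block")
        for eps in self.prep_efficiencies:
            if not all(-1.0 <= e <= 1.0 for e in eps):
                raise ValueError(f"inversion efficiencies must lie in [-1, 1], got {eps}")
        if self.prep_timing not in ("start", "mid", "end"):
            raise ValueError(f"unknown prep_timing {self.prep_timing!r}")

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ";".join(
                    ",".join(str(x) for x in e) if isinstance(e, tuple) else str(e)
                    for e in v
                )
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SequenceConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        for line in io.StringIO(text):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown sequence config key {key!r}")
            if key in ("prep_carriers_ppm", "prep_pi_efficiencies"):
                kwargs[key] = tuple(float(x) for x in raw.split(";"))
            elif key == "prep_efficiencies":
                kwargs[key] = tuple(
                    tuple(float(x) for x in e.split(",")) for e in raw.split(";")
                )
            elif key == "n_per_block":
                kwargs[key] = int(raw)
            elif key == "prep_timing":
                kwargs[key] = raw
            else:
                kwargs[key] = float(raw)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ScheduleEvent:
    """One entry of the timed event list; ``time`` is the event start (s)."""

    time: float
    pulse: PulseSpec
    block: int = 0
    fa_index: int = 0  # global 1..800 for excitations, else 0
    x: int = 0  # in-block 1..200
    target: str = ""
    meta: dict = field(default_factory=dict)


def build_fa_pattern(config: SequenceConfig | None = None) -> list[tuple[float, float, str]]:
    """Return the 800 (flip°, rf_phase°, target) tuples of the input pattern.

    Flip angles follow A·sin(π/200·x)^0.6 for x = 1..200 in each block with
    A = 35° (PCr blocks 1, 3) and A = 25° (ATP blocks 2, 4); the RF phase
    alternates 0°/180° across the whole train.
    """
    cfg = config or SequenceConfig()
    n = cfg.n_per_block
    out: list[tuple[float, float, str]] = []
    for block in range(1, N_BLOCKS + 1):
        pcr = block % 2 == 1
        amp = cfg.a_pcr if pcr else cfg.a_atp
        target = "PCr" if pcr else "ATP"
        for x in range(1, n + 1):
            flip = amp * math.sin(math.pi * x / n) ** 0.6
            phase = 180.0 * (len(out) % 2)
            out.append((flip, phase, target))
    return out


@dataclass
class AcquisitionSchedule:
    """Ordered event list of one FA-pattern repetition plus per-excitation metadata."""

    config: SequenceConfig
    events: list[ScheduleEvent]
    flip: np.ndarray  # (800,) degrees
    rf_phase: np.ndarray  # (800,) degrees
    target: np.ndarray  # (800,) '<U3'
    block: np.ndarray  # (800,) 1..4
    fa_index: np.ndarray  # (800,) global 1..800
    x: np.ndarray  # (800,) in-block 1..200
    tr: np.ndarray  # (800,) seconds
    te: np.ndarray  # (800,) effective delay pulse-end -> sample (incl. Te+)
    has_te_plus: np.ndarray  # (800,) bool

    @property
    def n_excitations(self) -> int:
        return len(self.flip)

    @property
    def total_duration(self) -> float:
        last = self.events[-1]
        return last.time + last.pulse.duration

    @property
    def pcr_mask(self) -> np.ndarray:
        return self.target == "PCr"

    def feasibility_audit(self) -> dict:
        """Check tr − te − pulse ≥ readout + refocus for every excitation.

        The printed timing leaves the readout + refocus window 0.12 ms short
        of the nominal TR; the audit reports the margin rather than raising.
        """
        cfg = self.config
        margin = self.tr - self.te - cfg.pulse_duration - (
            cfg.readout_duration + cfg.refocus_delay
        )
        return {
            "margin_s": margin,
            "feasible": bool(np.all(margin >= 0)),
            "worst_margin_s": float(margin.min()),
        }


def build_schedule(config: SequenceConfig | None = None) -> AcquisitionSchedule:
    """Construct the full timed event list of one pattern repetition."""
    cfg = config or SequenceConfig()
    cfg.validate()

    pattern = build_fa_pattern(cfg)
    n = cfg.n_per_block

    events: list[ScheduleEvent] = []
    flip = np.empty(len(pattern))
    rf_phase = np.empty(len(pattern))
    target = np.empty(len(pattern), dtype="<U3")
    blocks = np.empty(len(pattern), dtype=int)
    fa_index = np.arange(1, len(pattern) + 1)
    xs = np.empty(len(pattern), dtype=int)
    trs = np.empty(len(pattern))
    tes = np.empty(len(pattern))
    te_plus = np.zeros(len(pattern), dtype=bool)

    t = 0.0
    i = 0
    for b in range(1, N_BLOCKS + 1):
        pcr = b % 2 == 1
        carrier = cfg.pcr_ppm if pcr else cfg.atp_ppm
        # preparation: inversion -> delay -> crusher
        prep = PulseSpec(
            "inversion",
            cfg.inv_duration,
            carrier_offset=cfg.prep_carriers_ppm[b - 1],
            shape={
                "profile": "asymmetric_inversion",
                # preps 1 and 3 mirror the profile of preps 2 and 4
                "mirrored": b % 2 == 1,
                "efficiencies": cfg.prep_efficiencies[b - 1],
                "pi_efficiency": cfg.prep_pi_efficiencies[b - 1],
            },
        )
        events.append(ScheduleEvent(t, prep, block=b))
        t += cfg.inv_duration
        events.append(
            ScheduleEvent(
                t,
                PulseSpec("delay", cfg.post_inv_delay),
                block=b,
                meta={"role": "post_inversion_delay"},
            )
        )
        t += cfg.post_inv_delay
        events.append(ScheduleEvent(t, PulseSpec("crusher", cfg.crusher_duration), block=b))
        t += cfg.crusher_duration

        block_start = t
        for x in range(1, n + 1):
            f, ph, tgt = pattern[i]
            has_plus = pcr and (x % 2 == 0)
            tr = cfg.tr2 if has_plus else cfg.tr1
            te_eff = cfg.te + (cfg.te_plus if has_plus else 0.0)
            pulse = PulseSpec(
                "excitation",
                cfg.pulse_duration,
                nominal_flip=f,
                rf_phase=ph,
                carrier_offset=carrier,
                shape={"profile": "gaussian", "fwhm_hz": cfg.pulse_fwhm_hz},
            )
            events.append(
                ScheduleEvent(
                    t,
                    pulse,
                    block=b,
                    fa_index=i + 1,
                    x=x,
                    target=tgt,
                    meta={"tr": tr, "te": te_eff, "block_start": block_start},
                )
            )
            events.append(
                ScheduleEvent(
                    t + cfg.pulse_duration + te_eff,
                    PulseSpec("readout", cfg.readout_duration, carrier_offset=carrier),
                    block=b,
                    fa_index=i + 1,
                    target=tgt,
                    meta={"block_start": block_start},
                )
            )
            flip[i], rf_phase[i], target[i] = f, ph, tgt
            blocks[i], xs[i] = b, x
            trs[i], tes[i], te_plus[i] = tr, te_eff, has_plus
            t += tr
            i += 1
        events.append(
            ScheduleEvent(
                t,
                PulseSpec("delay", cfg.block_pause),
                block=b,
                meta={"role": "block_pause"},
            )
        )
        t += cfg.block_pause

    events.sort(key=lambda e: (e.time, e.pulse.kind == "readout"))
    return AcquisitionSchedule(
        config=cfg,
        events=events,
        flip=flip,
        rf_phase=rf_phase,
        target=target,
        block=blocks,
        fa_index=fa_index,
        x=xs,
        tr=trs,
        te=tes,
        has_te_plus=te_plus,
    )
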
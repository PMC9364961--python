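"""Sleep-stage vocabulary and canonical EEG rhythm bands.

The package scores sleep in the five-stage AASM scheme: wake (W), light
sleep (N1, N2), deep sleep (N3) and rapid eye movement (REM).  Every module
uses the same fixed stage order, W=0 .. REM=4, so confusion matrices, label
vectors and reports are always aligned.
"""

from __future__ import annotations

import enum


class StageLabel(enum.IntEnum):
    """AASM sleep stage with a stable integer code (W=0 .. REM=4)."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4

    @classmethod
    def from_name(cls, name: str) -> "StageLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown sleep stage {name!r}; expected one of "
                f"{[s.name for s in cls]} (five-stage AASM scheme)"
            ) from None


#: Fixed stage order used for confusion matrices and reports.
STAGE_ORDER: tuple[StageLabel, ...] = (
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.REM,
)

N_STAGES = len(STAGE_ORDER)

#: Canonical scalp-EEG rhythm bands (Hz): delta, theta, alpha, beta.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
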
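"""Canonical cardiac-sensing channel set and alias handling.

The model is channel-agnostic: every record's channels are mapped onto a
fixed 13-slot canonical ordering (the 12 standard ECG leads plus PPG), and
the channel-embedding table is indexed by this canonical id regardless of
which subset a record actually contains.
"""

from __future__ import annotations

CANONICAL_CHANNELS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6", "PPG",
)

N_CHANNELS = len(CANONICAL_CHANNELS)

CHANNEL_IDS: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_CHANNELS)}

# Case-insensitive alias table for common header spellings (user-extensible
# via `register_alias`).  "MLII" is the modified lead II used by ambulatory
# monitors; "PLETH" is the usual monitor label for the PPG waveform.
CHANNEL_ALIASES: dict[str, str] = {
    "mlii": "II", "ml2": "II", "lead ii": "II", "lead2": "II",
    "pleth": "PPG", "ppg": "PPG", "spo2": "PPG",
    "avr": "aVR", "avl": "aVL", "avf": "aVF",
    **{name.lower(): name for name in CANONICAL_CHANNELS},
}


def register_alias(alias: str, canonical: str) -> None:
    if canonical not in CHANNEL_IDS:
        raise ValueError(f"{canonical!r} is not a canonical channel")
    CHANNEL_ALIASES[alias.lower()] = canonical


def canonical_name(name: str) -> str | None:
    """Map a header channel label to its canonical name, or None if unknown."""
    return CHANNEL_ALIASES.get(name.strip().lower())


def channel_id(name: str) -> int:
    """Canonical integer id of a channel name (exact canonical spelling)."""
    try:
        return CHANNEL_IDS[name]
    except KeyError:
        raise ValueError(
            f"unknown channel {name!r}; canonical channels are {CANONICAL_CHANNELS}"
        ) from None
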
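"""Dose arithmetic for translating a human decoction dose to rodents.

A daily extract volume prepared for a reference adult is first expressed
per kilogram of body weight, then scaled by the standard human-to-mouse
allometric factor (~13x, reflecting the higher murine metabolic rate).
Worked example: a 270 mL daily decoction for a 60 kg adult is 4.5 mL/kg,
which corresponds to 58.5 mL/kg in the mouse.
"""
from __future__ import annotations


def dose_per_kg(total_volume_ml: float, body_weight_kg: float) -> float:
    """Volume dose normalised to body weight, in mL/kg."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if total_volume_ml < 0:
        raise ValueError("dose volume must be non-negative")
    return total_volume_ml / body_weight_kg


def allometric_scale(dose_per_kg_value: float, factor: float = 13.0) -> float:
    """Scale a per-kg dose across species by a metabolic-rate factor."""
    if factor <= 0:
        raise ValueError("allometric factor must be positive")
    return dose_per_kg_value * factor
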
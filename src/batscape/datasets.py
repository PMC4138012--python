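"""Published reference composition of the eastern-German noctule casualty set.

The original study classified 136 *Nyctalus noctula* carcasses from 45 wind
farms into 37 migratory and 99 sedentary individuals and reported their
composition by sex and age class together with group mean +/- SD fur
deuterium.  Those printed group counts and moments are embedded here so that
desk-level arithmetic (composition percentages, per-facility averages) can
be recomputed without the raw per-individual measurements, which were never
released as machine-readable data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_composition", "reference_records", "N_SITES", "N_RECORDS"]

N_RECORDS = 136
N_SITES = 45

# status, age, n_male, n_female, mean_male, mean_female (permil; None = not printed)
_COMPOSITION = [
    ("migratory", "adult", 6, 15, -115.4, -125.4),
    ("migratory", "juvenile", 6, 6, -108.9, -118.9),
    ("migratory", "NA", 2, 2, None, None),
    ("sedentary", "adult", 9, 16, -91.7, -98.2),
    ("sedentary", "juvenile", 18, 20, -96.3, -95.4),
    ("sedentary", "NA", 20, 16, -89.7, -88.4),
]

# whole-status fallback means used for age classes without printed values
_STATUS_MEANS = {("migratory", "male"): -111.7, ("migratory", "female"): -122.5}


def reference_composition() -> pd.DataFrame:
    """Published counts (and group mean fur values) by status x age x sex."""
    return pd.DataFrame(
        _COMPOSITION,
        columns=["status", "age", "n_male", "n_female", "mean_male", "mean_female"],
    )


def reference_records() -> pd.DataFrame:
    """Synthetic per-individual expansion of the published group counts.

    Each row is one individual with its published status/sex/age cell; the
    fur value attached is the *group mean* (or the whole-status mean where
    no group mean was printed), not a real measurement — sufficient for
    count and percentage arithmetic, not for refitting models.
    """
    rows = []
    k = 0
    for status, age, n_m, n_f, mean_m, mean_f in _COMPOSITION:
        for sex, n, mean in (("male", n_m, mean_m), ("female", n_f, mean_f)):
            if mean is None:
                mean = _STATUS_MEANS.get((status, sex))
            for _ in range(n):
                k += 1
                rows.append(
                    {
                        "id": f"R{k:03d}",
                        "status": status,
                        "sex": sex,
                        "age": age,
                        "d2h_fur": mean,
                    }
                )
    df = pd.DataFrame(rows)
    assert len(df) == N_RECORDS
    return df
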
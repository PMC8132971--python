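"""Fixed vocabularies: home regions, sensor types, activity label sets, score names.

These vocabularies define the schema of every downstream artifact (feature
vectors, marker tables, behaviorome columns), so their ordering is part of the
package contract and must never be reordered between releases.
"""

from __future__ import annotations

# Regions of the home used to identify ambient sensors.
HOME_REGIONS: tuple[str, ...] = (
    "Bathroom",
    "Bedroom",
    "DiningRoom",
    "Entry",
    "Hall",
    "Kitchen",
    "LivingRoom",
    "Office",
    "Other",
)

SENSOR_TYPES: tuple[str, ...] = ("Motion", "Door", "Temperature", "Light")

# Primary activity vocabulary recognized from ambient (smart home) data.
HOME_ACTIVITIES: tuple[str, ...] = (
    "Bed-toilet transition",
    "Cook",
    "Eat",
    "Enter home",
    "Leave home",
    "Personal hygiene",
    "Relax",
    "Sleep",
    "Wash dishes",
    "Work",
)

# Primary activity vocabulary recognized from wearable (smartwatch) data.
MOBILE_ACTIVITIES: tuple[str, ...] = (
    "Chores",
    "Eat",
    "Entertainment",
    "Errands",
    "Exercise",
    "Hobby",
    "Hygiene",
    "Relax",
    "School",
    "Sleep",
    "Travel",
    "Work",
)

# Specialized context categories detected by dedicated one-class classifiers.
ONE_CLASS_CATEGORIES: tuple[str, ...] = (
    "airplane",
    "art",
    "bathe",
    "beach",
    "biking",
    "bus",
    "car",
    "chores",
    "church",
    "computer",
    "cook",
    "dress",
    "drink",
    "entertainment",
    "groom",
    "hobby",
    "lunch",
    "movie",
    "music",
    "relax",
    "restaurant",
    "school",
    "service",
    "shop",
    "socialize",
    "sport",
)

LOCATION_TYPES: tuple[str, ...] = ("home", "road", "work", "other")

# Target clinical scores, in fixed reporting order.
TARGET_SCORES: tuple[str, ...] = ("WTAR", "TICS", "RBANS", "FAS", "TUG", "DEX", "ADLC")

# Watch channels carried on every 1 Hz sample.
WATCH_CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz", "course", "speed")
ACCEL_CHANNELS: tuple[str, ...] = ("ax", "ay", "az")
GYRO_CHANNELS: tuple[str, ...] = ("gx", "gy", "gz")

# Time-of-day bins used for frequented-location context features.
TIME_OF_DAY_BINS: tuple[str, ...] = ("night", "morning", "afternoon", "evening")


def time_of_day_bin(hour: float) -> str:
    """Map an hour past midnight onto one of the four coarse day segments."""
    if hour < 6:
        return "night"
    if hour < 12:
        return "morning"
    if hour < 18:
        return "afternoon"
    return "evening"


def sensor_key(region: str, sensor_type: str) -> str:
    return f"{region}-{sensor_type}"


#: All (region, type) sensor keys in canonical order.
SENSOR_KEYS: tuple[str, ...] = tuple(
    sensor_key(r, t) for r in HOME_REGIONS for t in SENSOR_TYPES
)
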
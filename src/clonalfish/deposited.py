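"""Adapter for externally deposited experiment data.

Published datasets arrive with their own column headers and units.  Rather
than hard-coding any particular deposit's names, a small YAML mapping file
translates external headers to the internal schema; a documented template
ships in ``docs/deposited_mapping.yaml``.

Expected layout of ``data_dir``::

    behavior file  -> DailyBehavior table (individual, day, activity, feeding)
    sizes file     -> weekly standard lengths (individual, age, length)
    broods file    -> brood records (individual, mother, age, count)
    offspring file -> long table of measured offspring lengths

Each section of the mapping names the file and maps internal column ->
external column; optional ``length_scale`` factors convert units (e.g. 0.1
for mm -> cm).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError

_SECTIONS = {
    "behavior": [
        "individual_id", "day", "activity_cm_per_s", "feeding_min",
    ],
    "sizes": ["individual_id", "age_days", "length_cm"],
    "broods": [
        "brood_id", "individual_id", "mother_id",
        "age_at_parturition_days", "brood_size",
    ],
    "offspring": ["brood_id", "individual_id", "offspring_length_cm"],
}

_SCALABLE = {"length_cm", "offspring_length_cm"}


def load_deposited(
    data_dir: str | Path, mapping_path: str | Path
) -> dict[str, pd.DataFrame]:
    """Load a deposited dataset through a column-mapping file.

    Returns tables keyed behavior/sizes/broods/offspring in the internal
    schema, ready for :func:`clonalfish.pipeline.analyze_tables`.
    """
    data_dir = Path(data_dir)
    mapping = yaml.safe_load(Path(mapping_path).read_text())
    if not isinstance(mapping, dict):
        raise ValidationError("mapping file must be a YAML mapping")
    out: dict[str, pd.DataFrame] = {}
    for section, required in _SECTIONS.items():
        sec = mapping.get(section)
        if sec is None:
            raise ValidationError(f"mapping missing section {section!r}")
        path = data_dir / sec["file"]
        if not path.exists():
            raise FileNotFoundError(f"deposited file not found: {path}")
        df = pd.read_csv(path)
        cols = sec.get("columns", {})
        missing = [c for c in required if c not in cols and c not in df.columns]
        if missing:
            raise ValidationError(
                f"{section}: no mapping or column for {missing}"
            )
        rename = {ext: internal for internal, ext in cols.items()}
        df = df.rename(columns=rename)
        scale = float(sec.get("length_scale", 1.0))
        if scale != 1.0:
            for c in _SCALABLE & set(df.columns):
                df[c] = df[c] * scale
        out[section] = df[[c for c in required if c in df.columns]
                          + [c for c in df.columns if c not in required]]
    return out
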
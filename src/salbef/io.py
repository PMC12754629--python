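"""Validated CSV readers/writers for the pipeline's tabular interfaces.

All tables are plain UTF-8 CSV with a mandatory header row and decimal-text
floats (full ``repr`` precision, so write→read round-trips are lossless in
float64).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

STRAINS_COLUMNS = ("strain_id", "genus", "s_opt", "sigma_tol", "y_max")
DESIGNS_COLUMNS = ("community_id", "group", "strain_id", "ry_expected")
MONOCULTURES_COLUMNS = ("strain_id", "salinity_pct", "yield")
OBSERVATIONS_COLUMNS = ("community_id", "group", "salinity_pct", "richness", "Y_O")
MEMBER_YIELDS_COLUMNS = ("community_id", "salinity_pct", "strain_id", "yield")
COMPOSITION_COLUMNS = ("community_id", "salinity_pct", "genus", "proportion")
PARTITION_COLUMNS = (
    "community_id", "salinity_pct", "N_retained", "Y_O", "Y_E", "NBE", "SE", "CE",
    "contribution_SE_pct", "contribution_CE_pct", "n_excluded",
)


def write_table(df: pd.DataFrame, path) -> None:
    # %.17g round-trips any float64 exactly through decimal text
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a CSV and check its header against the declared schema.

    Raises :class:`SchemaError` naming the missing column(s); extra columns
    are preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV: report with file context
        raise SchemaError(path, message=f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(path, missing=missing)
    return df
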
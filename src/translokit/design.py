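"""Experimental design: channel → sample mapping for TMT 10-plex sets.

One 10-plex set carries the 9 samples of one donor (3 subcellular fractions
× 3 stimulation timepoints) plus a pooled internal-standard channel (131)
shared across all sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: TMT 10-plex reporter channels in mass order.
CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")

#: Internal-standard channel: the pooled sample shared by every set.
INTERNAL_STANDARD_CHANNEL = "131"

#: Subcellular fractions: cytosol, membrane (incl. organelles), nucleus.
FRACTIONS = ("C", "M", "N")

#: Stimulation timepoints in minutes (rest, 15 min, 60 min).
TIMEPOINTS = (0, 15, 60)

DESIGN_COLUMNS = ["set_id", "channel", "donor", "fraction", "timepoint_min", "is_internal_standard"]


def sample_id(set_id: str, donor: str, fraction: str, timepoint_min: int) -> str:
    """Canonical sample-column name used in quantification matrices."""
    return f"{set_id}:{donor}:{fraction}:{timepoint_min}"


class ExperimentDesign:
    """Maps (set_id, channel) to (donor, fraction, timepoint).

    Exactly one internal-standard channel per set; within a set every
    (donor, fraction, timepoint) triple appears exactly once.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(DESIGN_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        table = table.copy()
        table["is_internal_standard"] = table["is_internal_standard"].astype(bool)
        self.table = table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for set_id, grp in self.table.groupby("set_id"):
            n_is = int(grp["is_internal_standard"].sum())
            if n_is != 1:
                raise ValueError(f"set {set_id}: expected exactly 1 internal-standard channel, got {n_is}")
            samples = grp.loc[~grp["is_internal_standard"]]
            triples = list(zip(samples["donor"], samples["fraction"], samples["timepoint_min"]))
            if len(triples) != len(set(triples)):
                raise ValueError(f"set {set_id}: duplicated (donor, fraction, timepoint) triple")
            bad_frac = set(samples["fraction"]) - set(FRACTIONS)
            if bad_frac:
                raise ValueError(f"set {set_id}: unknown fractions {sorted(bad_frac)}")

    @classmethod
    def from_tsv(cls, path) -> "ExperimentDesign":
        # keep empty strings (the internal-standard row has no fraction/donor)
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def set_ids(self) -> list:
        return sorted(self.table["set_id"].unique())

    def internal_standard_channel(self, set_id) -> str:
        grp = self.table[(self.table["set_id"] == set_id) & self.table["is_internal_standard"]]
        if grp.empty:
            raise KeyError(f"no internal-standard channel for set {set_id}")
        return str(grp["channel"].iloc[0])

    def sample_channels(self, set_id) -> pd.DataFrame:
        """Non-internal-standard channels of one set, with a sample_id column."""
        grp = self.table[(self.table["set_id"] == set_id) & ~self.table["is_internal_standard"]].copy()
        grp["sample_id"] = [
            sample_id(s, d, f, int(t))
            for s, d, f, t in zip(grp["set_id"], grp["donor"], grp["fraction"], grp["timepoint_min"])
        ]
        return grp

    def sample_table(self) -> pd.DataFrame:
        """All sample channels across sets with sample_id annotation."""
        return pd.concat([self.sample_channels(s) for s in self.set_ids], ignore_index=True)


@dataclass(frozen=True)
class DesignContrast:
    """Within-fraction, donor-paired contrast of a treatment timepoint vs rest."""

    fraction: str
    treatment: int
    baseline: int = 0

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.baseline == self.treatment:
            raise ValueError("baseline and treatment timepoints must differ")

    @property
    def name(self) -> str:
        return f"{self.treatment}min_vs_{self.baseline}min"
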
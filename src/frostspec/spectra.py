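"""SpectrumSet: a labelled matrix of spectra.

Rows are spectra (per-seed means or per-pixel samples), columns are bands on a
shared wavelength axis.  Row metadata (seed id, freeze-damage category label
1/2/3, pixel coordinates, variety tag) travels in a pandas DataFrame aligned
with the rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet"]

_META_COLUMNS = ("seed_id", "label", "x", "y", "variety")
VALID_LABELS = (1, 2, 3)


@dataclass
class SpectrumSet:
    values: np.ndarray                     # (N, B)
    wavelengths: np.ndarray                # (B,)
    meta: pd.DataFrame | None = None       # N rows; columns from _META_COLUMNS

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"{self.values.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=range(self.values.shape[0]))
        else:
            self.meta = self.meta.reset_index(drop=True)
            if len(self.meta) != self.values.shape[0]:
                raise ValueError("meta rows do not match spectra rows")
        if "label" in self.meta:
            labels = self.meta["label"].dropna()
            if not labels.isin(VALID_LABELS).all():
                raise ValueError("labels must be in {1, 2, 3}")

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        if "label" not in self.meta:
            raise ValueError("spectrum set has no category labels")
        return self.meta["label"].to_numpy(dtype=int)

    def with_values(self, values: np.ndarray, wavelengths=None) -> "SpectrumSet":
        """Same metadata, new matrix (used by pretreatment/selection steps)."""
        wl = self.wavelengths if wavelengths is None else wavelengths
        return SpectrumSet(values, wl, self.meta.copy())

    def subset(self, rows) -> "SpectrumSet":
        rows = np.asarray(rows)
        return SpectrumSet(
            self.values[rows], self.wavelengths, self.meta.iloc[rows].copy()
        )

    def concat(self, other: "SpectrumSet") -> "SpectrumSet":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("wavelength axes differ")
        return SpectrumSet(
            np.vstack([self.values, other.values]),
            self.wavelengths,
            pd.concat([self.meta, other.meta], ignore_index=True),
        )

    # -- CSV round trip -----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{w:.4f}" for w in self.wavelengths])
        for col in _META_COLUMNS:
            if col in self.meta:
                df.insert(0, col, self.meta[col].to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path)
        meta_cols = [c for c in _META_COLUMNS if c in df.columns]
        meta = df[meta_cols] if meta_cols else None
        spec_cols = [c for c in df.columns if c not in _META_COLUMNS]
        wavelengths = np.array([float(c) for c in spec_cols])
        return cls(df[spec_cols].to_numpy(dtype=float), wavelengths, meta)
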
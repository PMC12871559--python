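"""Synthetic initial-rate datasets under any inhibition model.

The default assay design mirrors a typical glycosidase inhibition study:
ten substrate concentrations spanning 0.625-25 mM, five inhibitor
concentrations 0-120 mM (an uninhibited reference plus a dose ladder), and
triplicate rate determinations per condition.  Noise is multiplicative
Gaussian (constant coefficient of variation) because initial rates span a
~40-fold range over such a design, making constant-CV far more realistic
than additive error; draws that would produce a non-positive rate are
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import GeneralParams, TraditionalParams
from .rate_laws import rate_general, traditional_rate

__all__ = ["AssayDesign", "RateDataset", "reference_design", "simulate_dataset"]

#: Ten-point substrate series, mM: the two-fold ladder 0.625-10 plus the
#: 25 mM top point, completed with midpoints to reach ten levels.
REFERENCE_S_MM = (0.625, 1.25, 1.875, 2.5, 3.75, 5.0, 7.5, 10.0, 17.5, 25.0)

#: Inhibitor dose ladder, mM, with the mandatory uninhibited reference.
REFERENCE_I_MM = (0.0, 20.0, 40.0, 80.0, 120.0)


@dataclass(frozen=True)
class AssayDesign:
    """Layout of an initial-rate inhibition assay.

    ``noise_cv`` is the coefficient of variation of the multiplicative rate
    noise; 0 gives exact model rates.  A seed is mandatory whenever
    ``noise_cv > 0`` so that no noisy dataset is silently non-reproducible.
    """

    S_values: tuple[float, ...] = REFERENCE_S_MM
    I_values: tuple[float, ...] = REFERENCE_I_MM
    replicates: int = 3
    noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S_values, dtype=float)
        I = np.asarray(self.I_values, dtype=float)
        if S.size < 2 or np.any(S <= 0):
            raise ValueError("need >= 2 substrate concentrations, all > 0")
        if np.any(I < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if 0.0 not in I:
            raise ValueError("the design must include the uninhibited reference I = 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_cv > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_cv > 0")
        object.__setattr__(self, "S_values", tuple(float(s) for s in S))
        object.__setattr__(self, "I_values", tuple(float(i) for i in I))

    @property
    def n_records(self) -> int:
        return len(self.S_values) * len(self.I_values) * self.replicates


def reference_design(noise_cv: float = 0.0, seed: int | None = None) -> AssayDesign:
    """The standard 10 x 5 x 3 design (see module docstring)."""
    return AssayDesign(noise_cv=noise_cv, seed=seed)


@dataclass
class RateDataset:
    """Initial-rate records with provenance.

    ``data`` has the canonical columns ``S_mM, I_mM, replicate, v0``.
    ``provenance`` records the generating parameters and seed for simulated
    data (empty for data read from file).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    REQUIRED_COLUMNS = ("S_mM", "I_mM", "replicate", "v0")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"rate data missing required columns: {missing}")
        if (self.data["v0"] <= 0).any():
            bad = int((self.data["v0"] <= 0).sum())
            raise ValueError(f"{bad} record(s) with non-positive v0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def I_levels(self) -> np.ndarray:
        return np.sort(self.data["I_mM"].unique())

    @property
    def S_levels(self) -> np.ndarray:
        return np.sort(self.data["S_mM"].unique())

    def mean_rates(self) -> pd.DataFrame:
        """Replicate-averaged rates per (S, I) condition."""
        return (
            self.data.groupby(["I_mM", "S_mM"], as_index=False)["v0"]
            .mean()
            .sort_values(["I_mM", "S_mM"], ignore_index=True)
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        """Read a rate table, mapping common column-name synonyms."""
        df = pd.read_csv(path)
        df = _canonicalise_columns(df)
        return cls(data=df)


_COLUMN_SYNONYMS = {
    "S_mM": {"s_mm", "s", "[s]", "substrate", "substrate_mm", "s_conc"},
    "I_mM": {"i_mm", "i", "[i]", "inhibitor", "inhibitor_mm", "i_conc"},
    "replicate": {"replicate", "rep", "replicate_index", "repeat"},
    "v0": {"v0", "v", "rate", "initial_rate", "velocity"},
}


def _canonicalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        for canonical, synonyms in _COLUMN_SYNONYMS.items():
            if key == canonical.lower() or key in synonyms:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def simulate_dataset(
    params: GeneralParams | TraditionalParams, design: AssayDesign
) -> RateDataset:
    """Generate an initial-rate dataset from a model under a design.

    Noiseless rates satisfy the reciprocal law exactly; with noise,
    v0 = true_rate * (1 + eps), eps ~ Normal(0, noise_cv), resampled while
    v0 <= 0.  Identical (params, design) including seed give byte-identical
    output.
    """
    rate_fn = rate_general if isinstance(params, GeneralParams) else traditional_rate
    S_grid, I_grid = np.meshgrid(design.S_values, design.I_values, indexing="ij")
    true_v = np.asarray(rate_fn(params, S_grid.ravel(), I_grid.ravel()))

    n_cond = true_v.size
    reps = design.replicates
    v0 = np.repeat(true_v, reps)
    if design.noise_cv > 0:
        rng = np.random.default_rng(design.seed)
        factors = 1.0 + rng.normal(0.0, design.noise_cv, size=v0.size)
        bad = factors <= 0
        while bad.any():  # truncate to positive rates by resampling
            factors[bad] = 1.0 + rng.normal(0.0, design.noise_cv, size=int(bad.sum()))
            bad = factors <= 0
        v0 = v0 * factors

    df = pd.DataFrame(
        {
            "S_mM": np.repeat(S_grid.ravel(), reps),
            "I_mM": np.repeat(I_grid.ravel(), reps),
            "replicate": np.tile(np.arange(reps), n_cond),
            "v0": v0,
        }
    )
    provenance = {
        "params": {k: v for k, v in vars(params).items() if not isinstance(v, dict)},
        "param_type": type(params).__name__,
        "design": {
            "S_values": list(design.S_values),
            "I_values": list(design.I_values),
            "replicates": design.replicates,
            "noise_cv": design.noise_cv,
            "seed": design.seed,
        },
    }
    if isinstance(params, TraditionalParams):
        provenance["params"]["mechanism"] = params.mechanism.value
    return RateDataset(data=df, provenance=provenance)
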
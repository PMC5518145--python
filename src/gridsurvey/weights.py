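"""Design weights for the growth approach to PSU formation.

The household base weight inverts the two selection probabilities — PSU i
selected PPES within stratum k, then household j sampled within the PSU:

    w_ij.b = (G_k / g_ik) / n_k * M_ik / m_ik

with an optional 1/b_ik factor when a manually drawn segment holds only a
fraction b_ik of the PSU's households.  Response weights invert the PSU- and
household-level response rates, with an extra individual factor u/u* for
individual-level weights.  The combined weights are the products
w_ij = w_ij.b * w_ij.r and w_ijq = w_ij.b * w_ijq.r.

Ledger input is a flat table with one row per household; individual rows
add the eligible/responding individual counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "WeightLedger",
    "household_base_weight",
    "segmented_base_weight",
    "household_response_weight",
    "individual_response_weight",
    "combined_weights",
]

LEDGER_COLUMNS = [
    "stratum_id",
    "psu_id",
    "household_id",
    "G_k",
    "g_ik",
    "n_k",
    "n_k_star",
    "M_ik",
    "m_ik",
    "m_ik_star",
    "b_ik",
    "u_ijk",
    "u_ijk_star",
]


def _positive(name: str, value: float) -> float:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return float(value)


def household_base_weight(G_k: float, g_ik: float, n_k: int, M_ik: float, m_ik: float) -> float:
    """Household selection (base) weight: (G_k/g_ik)/n_k * M_ik/m_ik."""
    _positive("g_ik", g_ik)
    _positive("n_k", n_k)
    _positive("m_ik", m_ik)
    return (G_k / g_ik) / n_k * (M_ik / m_ik)


def segmented_base_weight(
    G_k: float, g_ik: float, n_k: int, M_ik: float, m_ik: float, b_ik: float
) -> float:
    """Base weight when only a manually drawn segment (share b_ik) is listed."""
    if not 0.0 < b_ik <= 1.0:
        raise ValueError(f"b_ik must lie in (0, 1], got {b_ik}")
    return household_base_weight(G_k, g_ik, n_k, M_ik, m_ik) / b_ik


def household_response_weight(n_k: int, n_k_star: int, m_ik: float, m_ik_star: float) -> float:
    """Household response weight: (n_k/n_k*) * (m_ik/m_ik*)."""
    _positive("n_k_star", n_k_star)
    _positive("m_ik_star", m_ik_star)
    return (n_k / n_k_star) * (m_ik / m_ik_star)


def individual_response_weight(
    n_k: int, n_k_star: int, m_ik: float, m_ik_star: float, u_ijk: float, u_ijk_star: float
) -> float:
    """Individual response weight: household response * (u_ijk/u_ijk*)."""
    _positive("u_ijk_star", u_ijk_star)
    return household_response_weight(n_k, n_k_star, m_ik, m_ik_star) * (u_ijk / u_ijk_star)


@dataclass
class WeightLedger:
    """Per-household (and optionally per-individual) fieldwork tallies.

    ``households`` has one row per household with the LEDGER_COLUMNS fields;
    ``b_ik`` defaults to 1 (no manual segmentation) and the individual
    columns ``u_ijk``/``u_ijk_star`` may be absent for household-only runs.
    """

    households: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.households.copy()
        if "b_ik" not in df.columns:
            df["b_ik"] = 1.0
        df["b_ik"] = df["b_ik"].fillna(1.0)
        required = [
            "stratum_id", "psu_id", "household_id",
            "G_k", "g_ik", "n_k", "n_k_star", "M_ik", "m_ik", "m_ik_star",
        ]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"ledger is missing columns: {missing}")
        bad = df[
            (df["n_k_star"] <= 0) | (df["n_k_star"] > df["n_k"])
            | (df["m_ik"] <= 0) | (df["m_ik"] > df["M_ik"])
            | (df["m_ik_star"] <= 0) | (df["m_ik_star"] > df["m_ik"])
            | (df["b_ik"] <= 0) | (df["b_ik"] > 1)
            | (df["g_ik"] <= 0) | (df["G_k"] < df["g_ik"])
        ]
        if not bad.empty:
            raise ValueError(
                f"{len(bad)} ledger rows violate the count invariants "
                f"(first bad household: {bad.iloc[0]['household_id']!r})"
            )
        self.households = df

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "WeightLedger":
        return cls(pd.read_csv(path))

    @property
    def has_individuals(self) -> bool:
        return {"u_ijk", "u_ijk_star"}.issubset(self.households.columns)


def combined_weights(ledger: WeightLedger) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Household and (when individual tallies exist) individual weight tables.

    Returns ``(household_table, individual_table_or_None)``.  The household
    table is keyed by (stratum_id, psu_id, household_id) and carries the base
    weight ``w_ij_b``, response weight ``w_ij_r``, and product ``w_ij``.
    """
    df = ledger.households
    base = (df["G_k"] / df["g_ik"]) / df["n_k"] * (df["M_ik"] / df["m_ik"]) / df["b_ik"]
    hh_resp = (df["n_k"] / df["n_k_star"]) * (df["m_ik"] / df["m_ik_star"])
    household = pd.DataFrame(
        {
            "stratum_id": df["stratum_id"],
            "psu_id": df["psu_id"],
            "household_id": df["household_id"],
            "w_ij_b": base,
            "w_ij_r": hh_resp,
            "w_ij": base * hh_resp,
        }
    )
    if not ledger.has_individuals:
        return household, None
    rows = df.dropna(subset=["u_ijk", "u_ijk_star"])
    if (rows["u_ijk_star"] <= 0).any() or (rows["u_ijk_star"] > rows["u_ijk"]).any():
        raise ValueError("individual tallies violate 0 < u_ijk_star <= u_ijk")
    ind_resp = (
        (rows["n_k"] / rows["n_k_star"])
        * (rows["m_ik"] / rows["m_ik_star"])
        * (rows["u_ijk"] / rows["u_ijk_star"])
    )
    ind_base = (
        (rows["G_k"] / rows["g_ik"]) / rows["n_k"] * (rows["M_ik"] / rows["m_ik"]) / rows["b_ik"]
    )
    individual = pd.DataFrame(
        {
            "stratum_id": rows["stratum_id"],
            "psu_id": rows["psu_id"],
            "household_id": rows["household_id"],
            "w_ijq_r": ind_resp,
            "w_ijq": ind_base * ind_resp,
        }
    )
    return household, individual
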
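"""Multi-state network statistics: frequencies, contact maps, correlations.

Given the per-state interaction networks of an ensemble, this module computes

* edge frequencies — the fraction of states in which each typed interaction
  occurs (useful to separate stable from dynamic contacts);
* probabilistic contact maps — a residue × residue matrix of the fraction of
  states in which a pair shares at least one edge of the chosen scope;
* contact-count matrices — residues × states counts of incident edges, the
  substrate for Pearson contact correlations between sequence positions;
* the corresponding correlation tables and ranked reports.

Positions whose contact count never varies across states carry no correlation
information; such pairs are flagged ``defined=False`` rather than silently
reported as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionNetwork, InteractionType
from .structures import ResidueKey

TypeScope = InteractionType | str  # an InteractionType or "all"


def _in_scope(edge_type: InteractionType, scope: TypeScope) -> bool:
    return scope == "all" or edge_type == scope


def sampled_state_count(duration: float, interval: float) -> int:
    """Number of states obtained by sampling a trajectory of ``duration`` at
    one frame per ``interval`` (same time units; e.g. 100 ns at 0.8 ns -> 125).
    """
    if duration <= 0 or interval <= 0:
        raise ValueError("duration and interval must be positive")
    return int(math.floor(duration / interval + 1e-9))


def subsample_states(networks: Sequence[InteractionNetwork], stride: int
                     ) -> list[InteractionNetwork]:
    """Every ``stride``-th per-state network, preserving time order."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return list(networks[::stride])


# ---------------------------------------------------------------------------
# frequencies


@dataclass
class EdgeFrequencyTable:
    """Occurrence counts of each distinct (source, target, type) edge."""

    n_states: int
    frame: pd.DataFrame  # source, target, type, count, frequency

    def __len__(self) -> int:
        return len(self.frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def edge_frequencies(networks: Sequence[InteractionNetwork]
                     ) -> EdgeFrequencyTable:
    """Count in how many states each typed edge occurs; frequency = count/n."""
    if not networks:
        raise ValueError("need at least one network")
    n = len(networks)
    counts: dict[tuple[ResidueKey, ResidueKey, InteractionType], int] = {}
    for net in networks:
        for ident in {e.identity() for e in net.edges}:
            counts[ident] = counts.get(ident, 0) + 1
    rows = [
        {"source": str(s), "target": str(t), "type": ty.value,
         "count": c, "frequency": c / n}
        for (s, t, ty), c in sorted(counts.items(),
                                    key=lambda kv: (kv[0][0], kv[0][1],
                                                    kv[0][2].value))
    ]
    frame = pd.DataFrame(rows, columns=["source", "target", "type",
                                        "count", "frequency"])
    return EdgeFrequencyTable(n_states=n, frame=frame)


def frequency_filter(table: EdgeFrequencyTable, min_freq: float = 0.0,
                     max_freq: float = 1.0) -> EdgeFrequencyTable:
    """Rows with min_freq <= frequency <= max_freq (both ends inclusive)."""
    if not 0.0 <= min_freq <= max_freq <= 1.0:
        raise ValueError(f"need 0 <= min <= max <= 1, "
                         f"got [{min_freq}, {max_freq}]")
    mask = (table.frame["frequency"] >= min_freq) \
        & (table.frame["frequency"] <= max_freq)
    return EdgeFrequencyTable(table.n_states,
                              table.frame[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# contact maps and counts


@dataclass
class ContactProbabilityMap:
    """P[i, j] = fraction of states in which residues i and j share an edge."""

    keys: list[ResidueKey]
    matrix: np.ndarray  # (n_res, n_res) in [0, 1], symmetric, zero diagonal
    type_scope: TypeScope = "all"

    def write_tsv(self, path: str | Path) -> None:
        labels = [str(k) for k in self.keys]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(
            path, sep="\t")


@dataclass
class ContactCountMatrix:
    """C[i, s] = number of in-scope edges incident to residue i in state s."""

    keys: list[ResidueKey]
    matrix: np.ndarray  # (n_res, n_states) non-negative ints
    type_scope: TypeScope = "all"

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=[str(k) for k in self.keys],
                     columns=[f"state_{s}" for s in
                              range(self.matrix.shape[1])]).to_csv(
            path, sep="\t")


def _key_index(networks: Sequence[InteractionNetwork]
               ) -> tuple[list[ResidueKey], dict[ResidueKey, int]]:
    keys = list(networks[0].nodes)
    index = {k: i for i, k in enumerate(keys)}
    for net in networks[1:]:
        if list(net.nodes) != keys:
            raise ValueError("networks do not share the ensemble's "
                             "residue ordering")
    return keys, index


def contact_probability_map(networks: Sequence[InteractionNetwork],
                            type_scope: TypeScope = "all"
                            ) -> ContactProbabilityMap:
    if not networks:
        raise ValueError("need at least one network")
    keys, index = _key_index(networks)
    n = len(keys)
    acc = np.zeros((n, n))
    for net in networks:
        seen = {(index[e.source], index[e.target]) for e in net.edges
                if _in_scope(e.type, type_scope)}
        for i, j in seen:
            acc[i, j] += 1
            acc[j, i] += 1
    acc /= len(networks)
    np.fill_diagonal(acc, 0.0)
    return ContactProbabilityMap(keys=keys, matrix=acc, type_scope=type_scope)


def contact_count_matrix(networks: Sequence[InteractionNetwork],
                         type_scope: TypeScope = "all") -> ContactCountMatrix:
    if not networks:
        raise ValueError("need at least one network")
    keys, index = _key_index(networks)
    mat = np.zeros((len(keys), len(networks)), dtype=int)
    for s, net in enumerate(networks):
        for e in net.edges:
            if _in_scope(e.type, type_scope):
                mat[index[e.source], s] += 1
                mat[index[e.target], s] += 1
    return ContactCountMatrix(keys=keys, matrix=mat, type_scope=type_scope)


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationTable:
    """Pearson r of contact counts across states, per position pair."""

    keys: list[ResidueKey]
    frame: pd.DataFrame  # position_i, position_j, pearson_r, n_states, defined

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["abs_r"] = out["pearson_r"].abs()
        out = out.sort_values(["defined", "abs_r"],
                              ascending=[False, False]).drop(columns="abs_r")
        out.to_csv(path, sep="\t", index=False)


def contact_correlation(counts: ContactCountMatrix,
                        binary: bool = False) -> CorrelationTable:
    """Pearson correlation across states for every position pair.

    With fewer than 3 states every pair is flagged undefined, as are pairs
    where either position's counts have zero variance. ``binary=True``
    correlates edge presence (count > 0) instead of raw counts.
    """
    mat = counts.matrix.astype(float)
    if binary:
        mat = (mat > 0).astype(float)
    n_pos, n_states = mat.shape
    enough = n_states >= 3
    variable = mat.std(axis=1) > 0 if enough else np.zeros(n_pos, dtype=bool)

    r_full = np.full((n_pos, n_pos), np.nan)
    idx = np.flatnonzero(variable)
    if enough and len(idx) >= 1:
        sub = np.corrcoef(mat[idx])
        sub = np.atleast_2d(sub)
        r_full[np.ix_(idx, idx)] = sub

    rows = []
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            defined = enough and variable[i] and variable[j]
            rows.append({
                "position_i": str(counts.keys[i]),
                "position_j": str(counts.keys[j]),
                "pearson_r": float(np.clip(r_full[i, j], -1.0, 1.0))
                if defined else float("nan"),
                "n_states": n_states,
                "defined": bool(defined),
            })
    frame = pd.DataFrame(rows, columns=["position_i", "position_j",
                                        "pearson_r", "n_states", "defined"])
    return CorrelationTable(keys=counts.keys, frame=frame)


def correlation_report(table: CorrelationTable, top_k: int = 20,
                       sign: str = "both") -> pd.DataFrame:
    """Defined rows ranked by |r| (ties -> lexicographic positions).

    sign: ``positive`` keeps r > 0, ``negative`` keeps r < 0, ``both`` keeps
    all defined rows.
    """
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"unknown sign filter {sign!r}")
    if table.frame.empty:
        raise ValueError("empty correlation table")
    df = table.frame[table.frame["defined"]].copy()
    if sign == "positive":
        df = df[df["pearson_r"] > 0]
    elif sign == "negative":
        df = df[df["pearson_r"] < 0]
    df["abs_r"] = df["pearson_r"].abs()
    df = df.sort_values(["abs_r", "position_i", "position_j"],
                        ascending=[False, True, True])
    return df.drop(columns="abs_r").head(top_k).reset_index(drop=True)


def edge_presence_series(networks: Sequence[InteractionNetwork]
                         ) -> pd.DataFrame:
    """Per-edge binary presence along the state (time) axis.

    One row per distinct typed edge, one ``state_<s>`` column per state — the
    time-dependent network trajectory, unsmoothed.
    """
    if not networks:
        raise ValueError("need at least one network")
    idents = sorted({e.identity() for net in networks for e in net.edges},
                    key=lambda t: (t[0], t[1], t[2].value))
    per_state = [{e.identity() for e in net.edges} for net in networks]
    rows = [
        {"source": str(s), "target": str(t), "type": ty.value,
         **{f"state_{i}": int((s, t, ty) in present)
            for i, present in enumerate(per_state)}}
        for (s, t, ty) in idents
    ]
    return pd.DataFrame(rows)
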
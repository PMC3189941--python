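"""Context-stratified sequence-divergence statistics.

Every compared column of every annotated ortholog pair is labeled with its
region (5'UTR / CDS / 3'UTR), CpG context and — inside the CDS — codon-
position degeneracy class.  Divergence per stratum is the pooled number of
substitutions divided by the number of base pairs compared (multiple hits at
one site are negligible at the sub-5% divergences this targets, so no
multiple-hit correction is applied); the quoted SE is the standard error of
per-locus divergence across loci.

CpG definition: a column is CpG-context if its base participates in a CG
dinucleotide in EITHER member's sequence (default).  This captures
deamination at ancestrally methylated sites after one lineage has mutated
away the CG; the stricter both-members rule is available via ``cpg_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotatedOrtholog
from .genetics import DEGENERACY, FOURFOLD, ND, is_stop, is_transition

SITE_COLUMNS = ["pair_id", "region", "pos_a", "base_a", "base_b", "cpg",
                "deg", "diff", "transition"]

#: degeneracy label for columns outside CDS
NONCODING = "noncoding"
#: CDS columns excluded from degeneracy strata (stop codons, N, class clash)
EXCLUDED = "excluded"


def _cpg_mask(seq: str, positions: np.ndarray) -> np.ndarray:
    out = np.zeros(len(positions), dtype=bool)
    n = len(seq)
    for k, p in enumerate(positions):
        b = seq[p]
        if b == "C" and p + 1 < n and seq[p + 1] == "G":
            out[k] = True
        elif b == "G" and p > 0 and seq[p - 1] == "C":
            out[k] = True
    return out


def classify_sites(annotated: AnnotatedOrtholog, cpg_mode: str = "either") -> pd.DataFrame:
    """Per-column site labels for one annotated pair.

    Columns containing N in either member are excluded entirely.  Degeneracy
    is assigned only when both members' codons imply the same class; stop
    codons and disagreeing classes are kept in the "all"/CpG tallies but
    excluded from nd/4d strata.
    """
    if cpg_mode not in ("either", "both"):
        raise ValueError("cpg_mode must be 'either' or 'both'")
    seq_a, seq_b = annotated.member_a.sequence, annotated.member_b.sequence
    frames = []
    pair_id = annotated.pair.id_a
    for region in annotated.regions:
        pos_a, pos_b = region.pos_a, region.pos_b
        base_a = np.array([seq_a[p] for p in pos_a])
        base_b = np.array([seq_b[p] for p in pos_b])
        keep = (base_a != "N") & (base_b != "N")
        cpg_a = _cpg_mask(seq_a, pos_a)
        cpg_b = _cpg_mask(seq_b, pos_b)
        cpg = (cpg_a | cpg_b) if cpg_mode == "either" else (cpg_a & cpg_b)
        if region.label == "cds":
            deg = _cds_degeneracy(seq_a, seq_b, annotated)
        else:
            deg = np.full(len(pos_a), NONCODING, dtype=object)
        diff = base_a != base_b
        ts = np.array([is_transition(a, b) if d else False
                       for a, b, d in zip(base_a, base_b, diff)])
        df = pd.DataFrame({
            "pair_id": pair_id, "region": region.label, "pos_a": pos_a,
            "base_a": base_a, "base_b": base_b, "cpg": cpg, "deg": deg,
            "diff": diff, "transition": ts,
        })
        frames.append(df[keep])
    return pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=SITE_COLUMNS)


def _cds_degeneracy(seq_a: str, seq_b: str, annotated: AnnotatedOrtholog) -> np.ndarray:
    (sa, ea) = annotated.member_a.cds
    (sb, eb) = annotated.member_b.cds
    n = ea - sa
    out = np.empty(n, dtype=object)
    for c in range(0, n, 3):
        cod_a = seq_a[sa + c: sa + c + 3]
        cod_b = seq_b[sb + c: sb + c + 3]
        for p in range(3):
            if is_stop(cod_a) or is_stop(cod_b):
                out[c + p] = EXCLUDED
                continue
            da = DEGENERACY.get((cod_a, p))
            db = DEGENERACY.get((cod_b, p))
            out[c + p] = da if (da is not None and da == db) else EXCLUDED
    return out


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

#: row groups of the divergence table and their site selectors
GROUPS = ("utr5", "cds", "nd", "4d", "utr3")
STRATA = ("all", "non-CpG", "CpG")


def _group_mask(df: pd.DataFrame, group: str) -> pd.Series:
    if group in ("utr5", "cds", "utr3"):
        return df["region"] == group
    if group == "nd":
        return (df["region"] == "cds") & (df["deg"] == ND)
    if group == "4d":
        return (df["region"] == "cds") & (df["deg"] == FOURFOLD)
    raise ValueError(f"unknown group {group!r}")


def compute_divergence(sites: pd.DataFrame, group: str, stratum: str) -> dict | None:
    """One divergence-table row: pooled %difference, per-locus SE, kb, ts/tv.

    Returns None when the stratum contains no compared sites.
    """
    sel = sites[_group_mask(sites, group)]
    if stratum == "CpG":
        sel = sel[sel["cpg"]]
    elif stratum == "non-CpG":
        sel = sel[~sel["cpg"]]
    n = len(sel)
    if n == 0:
        return None
    subs = int(sel["diff"].sum())
    ts = int(sel["transition"].sum())
    tv = subs - ts
    per_locus = sel.groupby("pair_id", observed=True)["diff"].mean()
    se = float(per_locus.std(ddof=1) / np.sqrt(len(per_locus))) \
        if len(per_locus) > 1 else float("nan")
    return {
        "group": group, "stratum": stratum,
        "pct_diff": 100.0 * subs / n,
        "mean_loci": 100.0 * float(per_locus.mean()),
        "se": 100.0 * se,
        "compared_kb": n / 1000.0,
        "ts_tv": (ts / tv) if tv > 0 else float("inf") if ts > 0 else float("nan"),
        "n_subs": subs, "n_ts": ts, "n_tv": tv, "n_sites": n,
    }


def composition(sites_or_seq, group: str | None = None) -> tuple[float, float]:
    """(%GC, %CpG) of a site table group or of a raw nucleotide string.

    For a raw string, %CpG is the fraction of bases participating in a CG
    dinucleotide.  For a site table, both members' bases at the compared
    columns enter %GC and the column CpG flags give %CpG.
    """
    if isinstance(sites_or_seq, str):
        seq = sites_or_seq
        if not seq:
            raise ValueError("empty sequence")
        unamb = [b for b in seq if b in "ACGT"]
        gc = 100.0 * sum(b in "GC" for b in unamb) / len(unamb)
        cpg = 100.0 * sum(_cpg_mask(seq, np.arange(len(seq)))) / len(seq)
        return gc, cpg
    sel = sites_or_seq if group is None else \
        sites_or_seq[_group_mask(sites_or_seq, group)]
    if len(sel) == 0:
        raise ValueError("no compared sites in region")
    bases = pd.concat([sel["base_a"], sel["base_b"]])
    gc = 100.0 * bases.isin(["G", "C"]).mean()
    cpg = 100.0 * sel["cpg"].mean()
    return float(gc), float(cpg)


@dataclass
class DivergenceTable:
    """Divergence-table statistics: one row per (group, stratum).

    ``rows`` columns: group, stratum, pct_diff, mean_loci, se, compared_kb,
    ts_tv (+ raw counts).  ``groups`` columns: group, gc_pct, cpg_pct, loci.
    """
    rows: pd.DataFrame
    groups: pd.DataFrame

    @classmethod
    def from_sites(cls, sites: pd.DataFrame) -> "DivergenceTable":
        rows = []
        ginfo = []
        for group in GROUPS:
            gmask = _group_mask(sites, group)
            if not gmask.any():
                continue
            gc, cpg = composition(sites, group)
            ginfo.append({"group": group, "gc_pct": gc, "cpg_pct": cpg,
                          "loci": sites[gmask]["pair_id"].nunique()})
            for stratum in STRATA:
                row = compute_divergence(sites, group, stratum)
                if row is not None:
                    rows.append(row)
        return cls(pd.DataFrame(rows), pd.DataFrame(ginfo))

    @classmethod
    def from_pct(cls, pct: dict[str, dict[str, float]]) -> "DivergenceTable":
        """Build a table skeleton from bare %difference values.

        ``pct`` maps group -> stratum -> percent difference; all other
        statistics are NaN.  Used for worked examples on published values.
        """
        rows = [{"group": g, "stratum": s, "pct_diff": v,
                 "mean_loci": np.nan, "se": np.nan, "compared_kb": np.nan,
                 "ts_tv": np.nan, "n_subs": np.nan, "n_ts": np.nan,
                 "n_tv": np.nan, "n_sites": np.nan}
                for g, strata in pct.items() for s, v in strata.items()]
        return cls(pd.DataFrame(rows), pd.DataFrame(columns=["group", "gc_pct",
                                                             "cpg_pct", "loci"]))

    def pct(self, group: str, stratum: str) -> float:
        sel = self.rows[(self.rows["group"] == group) &
                        (self.rows["stratum"] == stratum)]
        if sel.empty:
            return float("nan")
        return float(sel["pct_diff"].iloc[0])

    def to_tsv(self, path) -> None:
        merged = self.rows.merge(self.groups, on="group", how="left")
        merged.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fold_ratios(table: DivergenceTable) -> dict[str, float]:
    """CpG/non-CpG divergence ratio per region group, plus the 4d/nd ratio.

    Undefined ratios (zero or missing denominator) are reported as NaN.
    """
    out: dict[str, float] = {}
    for group in GROUPS:
        num = table.pct(group, "CpG")
        den = table.pct(group, "non-CpG")
        out[f"{group}_cpg_vs_noncpg"] = num / den if den and den > 0 else float("nan")
    nd_all = table.pct("nd", "all")
    fd_all = table.pct("4d", "all")
    out["4d_vs_nd"] = fd_all / nd_all if nd_all and nd_all > 0 else float("nan")
    return out
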
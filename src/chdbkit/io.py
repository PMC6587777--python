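"""Readers and writers for the pipeline's tabular and sequence formats.

FASTA records carry their ids verbatim; genotype, fin-ray and embryo tables
are plain TSV/CSV read through pandas.  Writers emit the derived quantities
(frequencies, test statistics, viabilities; morphometric scores; expression
proportions) alongside the inputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .datatypes import GenotypeCounts
from .embryo import EmbryoMeasurement, blastopore_closure, szl_proportion
from .morphometrics import FinRayRecord, classify
from .segregation import estimate_frequencies, estimate_viability, mendelian_test, pool
from .sequence import CodingSequence, SnpRecord


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# --- FASTA ------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_coding_sequence(path, record_id: str | None = None) -> CodingSequence:
    """One FASTA record as a CodingSequence (the only record, or by id)."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} holds {len(records)} records; pass record_id to choose one"
            )
        record_id = next(iter(records))
    if record_id not in records:
        raise KeyError(f"record {record_id!r} not found in {path}")
    return CodingSequence(id=record_id, residues=records[record_id])


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# --- SNP tables -------------------------------------------------------------


def write_snp_table(path, snps: list[SnpRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "position": s.position,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "codon_index": s.codon_index,
                "codon_position": s.codon_position,
                "effect": s.effect,
            }
            for s in snps
        ],
        columns=["position", "ref", "alt", "codon_index", "codon_position", "effect"],
    )
    df.to_csv(path, sep=_sep(Path(path)), index=False)


# --- genotype count tables --------------------------------------------------


def read_genotype_tables(path) -> list[GenotypeCounts]:
    """Table with columns strain_id (or strain/label), n11, n12, n22."""
    df = pd.read_csv(path, sep=_sep(Path(path)))
    label_col = next(
        (c for c in ("strain_id", "strain", "label") if c in df.columns), None
    )
    if label_col is None or not {"n11", "n12", "n22"} <= set(df.columns):
        raise ValueError("genotype table needs columns strain_id, n11, n12, n22")
    return [
        GenotypeCounts(
            n11=int(r["n11"]), n12=int(r["n12"]), n22=int(r["n22"]), label=str(r[label_col])
        )
        for _, r in df.iterrows()
    ]


def segregation_report(
    tables: list[GenotypeCounts],
    expected=(0.25, 0.5, 0.25),
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Per-table (plus pooled) frequencies, chi-square test and viabilities."""
    rows = list(tables)
    if include_pooled and len(tables) > 1:
        rows.append(pool(tables))
    out = []
    for counts in rows:
        freq = estimate_frequencies(counts)
        row = {
            "strain_id": counts.label,
            "n11": counts.n11,
            "n12": counts.n12,
            "n22": counts.n22,
            "n": counts.total,
            "freq_11": freq.genotype_freqs[0],
            "freq_12": freq.genotype_freqs[1],
            "freq_22": freq.genotype_freqs[2],
            "allele2_freq": freq.allele2_freq,
        }
        try:
            test = mendelian_test(counts, expected)
            row.update(chi_square=test.chi_square, df=test.df, p_value=test.p_value)
        except ValueError:
            row.update(chi_square=float("nan"), df=2, p_value=float("nan"))
        try:
            w = estimate_viability(counts, expected)
            row.update(w11=w.w11, w12=w.w12, w22=w.w22)
        except ValueError:
            row.update(w11=float("nan"), w12=float("nan"), w22=float("nan"))
        out.append(row)
    return pd.DataFrame(out)


# --- fin-ray tables ---------------------------------------------------------


def read_finray_table(path) -> list[FinRayRecord]:
    """Table with columns fish_id (or id), genotype, cfrM, cfrL, cfrR."""
    df = pd.read_csv(path, sep=_sep(Path(path)), dtype={"genotype": str})
    id_col = "fish_id" if "fish_id" in df.columns else "id"
    return [
        FinRayRecord(
            fish_id=str(r[id_col]),
            genotype=str(r["genotype"]),
            cfrM=int(r["cfrM"]),
            cfrL=int(r["cfrL"]),
            cfrR=int(r["cfrR"]),
        )
        for _, r in df.iterrows()
    ]


def score_finray_table(records: list[FinRayRecord], threshold: int = 20) -> pd.DataFrame:
    """Input columns plus index, tail type and ray-count group per fish."""
    rows = []
    for rec in records:
        c = classify(rec, threshold)
        rows.append(
            {
                "fish_id": rec.fish_id,
                "genotype": rec.genotype,
                "cfrM": rec.cfrM,
                "cfrL": rec.cfrL,
                "cfrR": rec.cfrR,
                "max_caudal_index": c.max_caudal_index,
                "tail_type": c.tail_type,
                "fin_count_group": c.fin_count_group,
            }
        )
    return pd.DataFrame(rows)


# --- embryo tables ----------------------------------------------------------


def read_embryo_table(path) -> list[EmbryoMeasurement]:
    """Table with columns embryo_id, treatment, szl_dv, emb_dv, bp_dv."""
    df = pd.read_csv(path, sep=_sep(Path(path)))
    return [
        EmbryoMeasurement(
            embryo_id=str(r["embryo_id"]),
            treatment=str(r["treatment"]),
            szl_dv=float(r["szl_dv"]),
            emb_dv=float(r["emb_dv"]),
            bp_dv=float(r["bp_dv"]),
        )
        for _, r in df.iterrows()
    ]


def score_embryo_table(
    measurements: list[EmbryoMeasurement], denominator: str = "bp"
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "embryo_id": m.embryo_id,
                "treatment": m.treatment,
                "szl_dv": m.szl_dv,
                "emb_dv": m.emb_dv,
                "bp_dv": m.bp_dv,
                "szl_proportion": szl_proportion(m),
                "blastopore_closure": blastopore_closure(m, denominator),
            }
        )
    return pd.DataFrame(rows)


# --- trajectories -----------------------------------------------------------


def trajectory_frame(trajectories: dict[float, "object"]) -> pd.DataFrame:
    """Long-format table (generation, q0, q, mean_fitness) from projections."""
    rows = []
    for q0, traj in trajectories.items():
        for g, (q, wbar) in enumerate(zip(traj.q, traj.mean_fitness)):
            rows.append(
                {"generation": g, "q0": q0, "q": float(q), "mean_fitness": float(wbar)}
            )
    return pd.DataFrame(rows)
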
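"""Readers, writers, pipeline configuration, and the end-to-end runner.

Native matrix format is TSV (individuals x markers, header row of SNP ids,
missing token "NA") for transparency at follow-up-study scale; VCF
ingestion is provided for interoperability (ALT is the coded allele).
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import global_from_local, ld_prune, map_test, thin_random
from .association import (
    AllStrataDegenerateError,
    conditional_scan,
    stratified_assoc,
)
from .finemap import adjust_p, best_snp, build_locus, region_length
from .phenotype import phenotype_pipeline
from .power import variance_partition_report
from .simulate import AdmixedCohort, AncestralPanel, SimTruth

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "read_local_ancestry",
    "read_phenotypes",
    "read_ancestral_panel",
    "read_ld_reference",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_local_tsv",
    "write_phenotype_tsv",
    "write_markers_tsv",
    "write_panel_tsv",
    "write_truth_yaml",
    "run_pipeline",
]

MISSING_TOKEN = "NA"


# ---------------------------------------------------------------------------
# configuration

_CONFIG_FIELDS: dict[str, tuple] = {}


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end analysis run."""

    genotypes: str
    local_ancestry: str
    phenotypes: str
    out_dir: str
    genotype_format: str = "tsv"
    markers: str | None = None
    ld_reference: str | None = None
    ancestral_panel: str | None = None
    index_snps: list[str] = field(default_factory=list)
    model: str = "additive"
    min_stratum_n: int = 10
    min_mac: int = 3
    r2_locus: float = 0.3
    prune_r2: float = 0.2
    thin_target: int = 10_000
    winsor_k: float = 3.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype_format not in ("tsv", "vcf"):
            raise ValueError(f"unknown genotype_format {self.genotype_format!r}")
        if self.model not in ("additive", "recessive"):
            raise ValueError(f"unknown model {self.model!r}")
        for name, lo, hi in (
            ("r2_locus", 0.0, 1.0),
            ("prune_r2", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.winsor_k <= 0:
            raise ValueError("winsor_k must be positive")
        if self.min_stratum_n < 2 or self.min_mac < 0:
            raise ValueError("invalid stratum size / MAC thresholds")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str = "tsv", markers_path=None):
    """Read a dosage matrix; returns (dosages n x m, markers frame, sample ids).

    markers frame columns: snp_id, pos, coded_allele.  TSV: individuals x
    markers with an ``id`` column and snp_id headers, positions from the
    optional markers file (sequential otherwise).  VCF: biallelic records
    only, the ALT allele is counted; multi-allelic sites are skipped with a
    warning.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], dtype={"id": str})
        if "id" not in df.columns:
            raise ValueError(f"{path}: genotype TSV must have an 'id' column")
        samples = df["id"].to_numpy()
        snp_ids = [c for c in df.columns if c != "id"]
        G = df[snp_ids].to_numpy(dtype=float)
        bad = np.flatnonzero(~(np.isnan(G) | np.isin(G, (0, 1, 2))).all(axis=0))
        if bad.size:
            raise ValueError(f"{path}: non-dosage values in column {snp_ids[bad[0]]!r}")
        if markers_path is not None:
            mk = pd.read_csv(markers_path, sep="\t", dtype={"snp_id": str})
            mk = mk.set_index("snp_id").loc[snp_ids].reset_index()
        else:
            mk = pd.DataFrame(
                {"snp_id": snp_ids, "pos": np.arange(1, len(snp_ids) + 1), "coded_allele": "A"}
            )
        return G, mk, samples
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, ids, pos, alleles = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        pos.append(var.POS)
        alleles.append(var.ALT[0])
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF record(s)", stacklevel=2)
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    G = np.column_stack(rows) if len(rows) > 1 else np.asarray(rows).T
    mk = pd.DataFrame({"snp_id": ids, "pos": pos, "coded_allele": alleles})
    return G, mk, samples


def read_local_ancestry(path, snp_ids, sample_ids) -> np.ndarray:
    """Local-ancestry TSV aligned by id to the genotype matrix.

    Same shape/convention as the genotype TSV; marker columns are realigned
    to ``snp_ids`` and rows to ``sample_ids``; any mismatch in the id sets
    fails fast with the offending ids enumerated.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: local-ancestry TSV must have an 'id' column")
    cols = [c for c in df.columns if c != "id"]
    missing_snps = sorted(set(map(str, snp_ids)) - set(cols))
    extra_snps = sorted(set(cols) - set(map(str, snp_ids)))
    if missing_snps or extra_snps:
        raise ValueError(
            f"{path}: marker mismatch (missing {missing_snps[:5]}, extra {extra_snps[:5]})"
        )
    df = df.set_index("id")
    missing_ind = sorted(set(map(str, sample_ids)) - set(df.index))
    if missing_ind:
        raise ValueError(f"{path}: individuals absent: {missing_ind[:5]}")
    L = df.loc[list(map(str, sample_ids)), list(map(str, snp_ids))].to_numpy(dtype=float)
    bad = ~(np.isnan(L) | np.isin(L, (0, 1, 2)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid local ancestry {L[i, j]!r} at individual "
            f"{sample_ids[i]!r}, marker {snp_ids[j]!r}"
        )
    return L


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate TSV: id, age, sex, creatinine and/or phenotype."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], dtype={"id": str})
    required = {"id", "age", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "creatinine" not in df.columns and "phenotype" not in df.columns:
        raise ValueError(f"{path}: need a creatinine or phenotype column")
    return df


def read_ancestral_panel(path) -> AncestralPanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    kw = {}
    if {"count_afr", "count_eur", "n_chrom_afr", "n_chrom_eur"} <= set(df.columns):
        kw = dict(
            count_afr=df["count_afr"].to_numpy(int),
            count_eur=df["count_eur"].to_numpy(int),
            n_chrom_afr=int(df["n_chrom_afr"].iloc[0]),
            n_chrom_eur=int(df["n_chrom_eur"].iloc[0]),
        )
    return AncestralPanel(
        snp_id=df["snp_id"].to_numpy(), pos=df["pos"].to_numpy(int),
        freq_afr=df["freq_afr"].to_numpy(float), freq_eur=df["freq_eur"].to_numpy(float),
        **kw,
    )


def read_ld_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    if not {"snp_a", "snp_b", "r2"} <= set(df.columns):
        raise ValueError(f"{path}: LD reference needs columns snp_a, snp_b, r2")
    return df


# ---------------------------------------------------------------------------
# writers


def _matrix_tsv(path, matrix, snp_ids, sample_ids, fmt="%g"):
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, snp_ids)) + "\n")
        for sid, row in zip(sample_ids, np.asarray(matrix)):
            vals = [MISSING_TOKEN if np.isnan(v) else fmt % v for v in row]
            fh.write(str(sid) + "\t" + "\t".join(vals) + "\n")


def write_genotypes_tsv(cohort: AdmixedCohort, path) -> None:
    _matrix_tsv(path, cohort.genotypes, cohort.snp_id, cohort.sample_id)


def write_local_tsv(cohort: AdmixedCohort, path) -> None:
    _matrix_tsv(path, cohort.local, cohort.snp_id, cohort.sample_id)


def write_markers_tsv(cohort: AdmixedCohort, path, coded_allele: str = "A") -> None:
    pd.DataFrame(
        {"snp_id": cohort.snp_id, "pos": cohort.pos, "coded_allele": coded_allele}
    ).to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(cohort: AdmixedCohort, path, chrom: str = "1") -> None:
    """Plain-text VCF with GT-coded dosages; ALT ('A') is the coded allele."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=admixstrat {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, cohort.sample_id)) + "\n"
        )
        for j in range(cohort.m):
            gts = [
                "./." if np.isnan(v) else gt_map[float(v)] for v in cohort.genotypes[:, j]
            ]
            fh.write(
                f"{chrom}\t{int(cohort.pos[j])}\t{cohort.snp_id[j]}\tG\tA\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_phenotype_tsv(cohort: AdmixedCohort, path) -> None:
    df = pd.DataFrame({"id": cohort.sample_id, "age": cohort.age, "sex": cohort.sex})
    if cohort.creatinine is not None:
        df["creatinine"] = cohort.creatinine
    if cohort.phenotype is not None:
        df["phenotype"] = cohort.phenotype
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def write_panel_tsv(panel: AncestralPanel, path) -> None:
    df = pd.DataFrame(
        {"snp_id": panel.snp_id, "pos": panel.pos,
         "freq_afr": panel.freq_afr, "freq_eur": panel.freq_eur}
    )
    if panel.count_afr is not None:
        df["count_afr"] = panel.count_afr
        df["count_eur"] = panel.count_eur
        df["n_chrom_afr"] = panel.n_chrom_afr
        df["n_chrom_eur"] = panel.n_chrom_eur
    df.to_csv(path, sep="\t", index=False)


def write_truth_yaml(truth: SimTruth, path) -> None:
    cfg = dataclasses.asdict(truth.config)
    cfg["causal_effects"] = dict(cfg["causal_effects"])
    doc = {
        "config": cfg,
        "freq_afr": [float(v) for v in truth.freq_afr],
        "freq_eur": [float(v) for v in truth.freq_eur],
        "theta": [float(v) for v in truth.theta],
        "snp_id": [str(s) for s in truth.snp_id],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run phenotype -> structure -> stratified association -> fine-mapping
    -> conditional scan -> variance partition; returns the run directory.

    Deterministic given ``cfg.seed``; every output is TSV or plain text with
    fixed column order, and the log records version, seed and config hash.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    log_lines = [
        f"admixstrat {__version__}",
        f"seed {cfg.seed}",
        f"config sha256 {hashlib.sha256(json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]}",
    ]

    G, markers, samples = read_genotypes(
        cfg.genotypes, format=cfg.genotype_format, markers_path=cfg.markers
    )
    snp_ids = markers["snp_id"].to_numpy()
    L = read_local_ancestry(cfg.local_ancestry, snp_ids, samples)
    pheno = read_phenotypes(cfg.phenotypes).set_index("id").loc[list(map(str, samples))]
    age = pheno["age"].to_numpy(float)
    sex = pheno["sex"].to_numpy(float)
    theta = global_from_local(L)

    # phenotype construction: serum creatinine, when present, takes precedence
    # so the run always documents its own MDRD -> Box-Cox -> winsorize trail
    if "creatinine" not in pheno.columns or pheno["creatinine"].isna().any():
        y = pheno["phenotype"].to_numpy(float)
        log_lines.append("phenotype: taken as provided (already transformed)")
    else:
        y, report = phenotype_pipeline(
            pheno["creatinine"].to_numpy(float), age, sex == 1, black=True, k=cfg.winsor_k
        )
        (out / "phenotype_report.txt").write_text(str(report) + "\n")
        log_lines.append(f"phenotype: MDRD + Box-Cox(lambda={report.lambda_hat:.4f}) + winsorize")

    # structure check
    kept = ld_prune(G, r2_max=cfg.prune_r2)
    thin = thin_random(kept, min(cfg.thin_target, len(kept)), seed=rng)
    structure = map_test(G[:, thin])
    (out / "structure_report.txt").write_text(str(structure) + "\n")
    log_lines.append(
        f"structure: {len(kept)} markers after pruning, {len(thin)} used, "
        f"{structure.n_significant_pcs} significant PC(s)"
    )

    # per-SNP stratified association
    rows = []
    fits = {}
    for j, sid in enumerate(snp_ids):
        try:
            fit = stratified_assoc(
                y, G[:, j], L[:, j], age, sex, theta, model=cfg.model,
                min_stratum_n=cfg.min_stratum_n, min_mac=cfg.min_mac,
                snp_id=str(sid), coded_allele=str(markers["coded_allele"].iloc[j]),
            )
        except AllStrataDegenerateError:
            continue
        fits[str(sid)] = fit
        row = {
            "snp_id": sid, "pos": int(markers["pos"].iloc[j]),
            "coded_allele": markers["coded_allele"].iloc[j], "model": cfg.model,
        }
        for s in (0, 1, 2):
            sf = fit.stratum.get(s)
            row[f"beta_{s}"] = sf.beta if sf else np.nan
            row[f"se_{s}"] = sf.se if sf else np.nan
            row[f"n_{s}"] = sf.n if sf else 0
        row.update(beta_meta=fit.beta_meta, se_meta=fit.se_meta, z=fit.z, p=fit.p)
        rows.append(row)
    assoc = pd.DataFrame(rows)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False, na_rep=MISSING_TOKEN)
    log_lines.append(f"association: {len(assoc)} of {len(snp_ids)} SNPs testable")

    # fine-mapping + conditional scans
    if cfg.index_snps and cfg.ld_reference:
        ld_ref = read_ld_reference(cfg.ld_reference)
        ref_pos = dict(zip(map(str, snp_ids), markers["pos"].astype(int)))
        if cfg.ancestral_panel:
            panel = read_ancestral_panel(cfg.ancestral_panel)
            ref_pos.update(dict(zip(map(str, panel.snp_id), map(int, panel.pos))))
        locus_rows, cond_rows = [], []
        cond_dosages = {}
        loci = {}
        for index in cfg.index_snps:
            locus = build_locus(
                index, ld_ref, ref_pos, ref_pos_subset(ref_pos, snp_ids),
                lambda s: G[:, int(np.flatnonzero(snp_ids == s)[0])],
                r2_min=cfg.r2_locus, alpha=cfg.alpha,
            )
            loci[index] = locus
            tested = {
                s: (fits[s].p, fits[s].z) for s in map(str, locus.members) if s in fits
            }
            if not tested:
                continue
            top = best_snp(tested)
            p_adj, thr = adjust_p(fits[top].p, locus.n_eff, alpha=cfg.alpha)
            member_pos = np.array([ref_pos[s] for s in tested])
            member_sig = np.array([adjust_p(p, locus.n_eff)[0] < cfg.alpha for p, _ in tested.values()])
            if member_sig.any() and not (member_sig[np.argmin(member_pos)] or member_sig[np.argmax(member_pos)]):
                length_kb = region_length(member_sig, member_pos) / 1000.0
            else:
                length_kb = np.nan
            locus_rows.append({
                "index_snp": index, "left": locus.bounds[0], "right": locus.bounds[1],
                "K": locus.K, "n_eff": locus.n_eff, "best_snp": top,
                "p_best": fits[top].p, "p_adjusted": p_adj, "threshold": thr,
                "significant": p_adj < cfg.alpha, "region_kb": length_kb,
            })
            # conditional scan within significant loci
            if p_adj < cfg.alpha and len(tested) > 1:
                cols = [int(np.flatnonzero(snp_ids == s)[0]) for s in tested]
                scan = conditional_scan(
                    y, G[:, cols], list(tested), top, L[:, cols], age, sex, theta,
                    model=cfg.model, min_stratum_n=cfg.min_stratum_n, min_mac=cfg.min_mac,
                )
                for sid, cfit in scan.items():
                    if cfit is None:
                        continue
                    cp_adj, _ = adjust_p(cfit.p, locus.n_eff, alpha=cfg.alpha)
                    cond_rows.append({
                        "index_snp": index, "snp_id": sid, "conditioned_on": top,
                        "beta_meta": cfit.beta_meta, "se_meta": cfit.se_meta,
                        "p": cfit.p, "p_adjusted": cp_adj, "secondary": cp_adj < cfg.alpha,
                    })
                    if cp_adj < cfg.alpha:
                        cond_dosages[sid] = G[:, int(np.flatnonzero(snp_ids == sid)[0])]
        loci_df = pd.DataFrame(locus_rows)
        loci_df.to_csv(out / "loci.tsv", sep="\t", index=False, na_rep=MISSING_TOKEN)
        pd.DataFrame(cond_rows).to_csv(
            out / "conditional.tsv", sep="\t", index=False, na_rep=MISSING_TOKEN
        )
        log_lines.append(f"finemap: {len(locus_rows)} loci, {len(cond_rows)} conditional tests")

        # variance partition over significant loci
        sig_best = [r["best_snp"] for r in locus_rows if r["significant"]]
        if sig_best:
            col = {s: int(np.flatnonzero(snp_ids == s)[0]) for s in sig_best}
            part = variance_partition_report(
                y, age, sex, theta,
                snp_dosages={s: G[:, c] for s, c in col.items()},
                snp_local={s: L[:, c] for s, c in col.items()},
                conditional_dosages=cond_dosages or None,
            )
            part.to_csv(out / "variance.tsv", sep="\t", index=False)
            log_lines.append("variance partition written")

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def ref_pos_subset(ref_pos: dict[str, int], snp_ids) -> dict[str, int]:
    """Positions restricted to genotyped cohort SNPs (locus membership)."""
    genotyped = set(map(str, snp_ids))
    return {s: p for s, p in ref_pos.items() if s in genotyped}
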
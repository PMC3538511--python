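"""Configuration parsing, tabular output dialects, run log and SNP map.

All tables are tab-delimited with a single header row.  Output rows carry,
left to right: disease status (1 affected, 0 unaffected, NA if unassigned),
gender (1/2, arbitrary labels), the causal environmental exposure, any noise
exposures, then the genetic columns in one of two dialects:

* phased — two columns per SNP holding nucleotide symbols (maternal/paternal
  order as generated);
* genotypic — one column per SNP holding codes 1/2/3, where 2 is the
  heterozygote and 3 is the high-risk homozygote for a DPL or the
  lower-frequency homozygote for any other SNP (ties at frequency 0.5 are
  broken lexicographically by allele symbol and noted in the log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .population import (
    EnvironmentSpec,
    HaplotypePanel,
    LocusSpec,
    NoiseVariableSpec,
    Population,
)
from .epistasis import EpistasisSpec, validate_epistasis_spec
from .gxe import GxeModel
from .simulate import CaseControlSample

ENV_COLUMN = "env"
_LEFT_COLUMNS = ("status", "gender")


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters (the tool's single source of truth)."""

    seed: int
    prevalence: float
    loci: tuple[LocusSpec, LocusSpec]
    environment: EnvironmentSpec
    gxe_model: GxeModel
    epistasis: EpistasisSpec = EpistasisSpec()
    noise: tuple[NoiseVariableSpec, ...] = ()
    n_individuals: int = 10_000
    panel_n_loci: int = 2
    panel_block_lengths: tuple[int, ...] = (1, 1)
    panel_within_block_r2: float = 0.0
    panel_allele_freqs: tuple[float, ...] | None = None
    panel_pool_size: int = 20_000
    use_panel: bool = False
    n_cases: int | None = None
    n_controls: int | None = None
    n_replicates: int = 1
    output_format: str = "genotypic"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if self.output_format not in ("genotypic", "phased"):
            raise ValidationError(
                f"output format must be 'genotypic' or 'phased', got {self.output_format!r}"
            )
        if self.loci[0].marker_id == self.loci[1].marker_id:
            raise ValidationError("the two DPLs must be distinct markers")
        validate_epistasis_spec(self.epistasis)
        if self.use_panel:
            if sum(self.panel_block_lengths) != self.panel_n_loci:
                raise ValidationError("panel block lengths must sum to panel n_loci")
            ids = {f"snp{j + 1:04d}" for j in range(self.panel_n_loci)}
            missing = [s.marker_id for s in self.loci if s.marker_id not in ids]
            if missing:
                raise ValidationError(
                    f"DPL marker id(s) {missing} do not exist among the panel "
                    f"markers snp0001..snp{self.panel_n_loci:04d} "
                    "(referential integrity)"
                )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        loci_raw = raw["loci"]
        if len(loci_raw) != 2:
            raise ValidationError(f"exactly two DPLs are required, got {len(loci_raw)}")
        loci = tuple(
            LocusSpec(
                marker_id=str(d["marker_id"]),
                high_risk_allele=str(d["high_risk_allele"]),
                allele_freq=float(d["allele_freq"]),
                rr=float(d["rr"]),
                w=float(d.get("dominance_w", d.get("w", 0.5))),
            )
            for d in loci_raw
        )
        env_raw = raw.get("environment", {})
        env = EnvironmentSpec(
            mean=float(env_raw.get("mean", 0.0)),
            sd=float(env_raw.get("sd", 1.0)),
            or_per_unit=float(env_raw.get("or_per_unit", 1.0)),
        )
        noise = tuple(
            NoiseVariableSpec(
                name=str(d["name"]), family=str(d["family"]), params=dict(d.get("params", {}))
            )
            for d in raw.get("noise", [])
        )
        panel = raw.get("panel") or {}
        sampling = raw.get("sampling") or {}
        freqs = panel.get("allele_freqs")
        if freqs is not None and not np.iterable(freqs):
            freqs = [float(freqs)] * int(panel.get("n_loci", 2))
        return RunConfig(
            seed=int(raw.get("seed", 0)),
            prevalence=float(raw["prevalence"]),
            loci=loci,  # type: ignore[arg-type]
            environment=env,
            gxe_model=GxeModel(str(raw.get("gxe_model", "ADD")).upper()),
            epistasis=EpistasisSpec.from_dicts(raw.get("epistasis", [])),
            noise=noise,
            n_individuals=int(raw.get("n_individuals", 10_000)),
            use_panel=bool(panel),
            panel_n_loci=int(panel.get("n_loci", 2)),
            panel_block_lengths=tuple(panel.get("block_lengths", (1, 1))),
            panel_within_block_r2=float(panel.get("within_block_r2", 0.0)),
            panel_allele_freqs=tuple(float(f) for f in freqs) if freqs else None,
            panel_pool_size=int(panel.get("pool_size", 20_000)),
            n_cases=int(sampling["n_cases"]) if "n_cases" in sampling else None,
            n_controls=int(sampling["n_controls"]) if "n_controls" in sampling else None,
            n_replicates=int(sampling.get("n_replicates", 1)),
            output_format=str(raw.get("output_format", "genotypic")),
        )
    except KeyError as exc:
        raise ValidationError(f"missing required configuration key: {exc}") from None


def _left_block(pop: Population, rows: np.ndarray) -> dict[str, np.ndarray]:
    n = rows.size
    status = (
        np.full(n, "NA", dtype=object)
        if pop.status is None
        else pop.status[rows].astype(object)
    )
    gender = (
        np.full(n, "NA", dtype=object)
        if pop.gender is None
        else pop.gender[rows].astype(object)
    )
    cols: dict[str, np.ndarray] = {"status": status, "gender": gender}
    if pop.exposure is not None:
        cols[ENV_COLUMN] = pop.exposure[rows]
    for name, values in pop.noise_exposures.items():
        cols[name] = values[rows]
    return cols


def _sample_rows(pop: Population, sample: CaseControlSample | None) -> np.ndarray:
    if sample is None:
        return np.arange(pop.n)
    return np.concatenate([sample.cases, sample.controls])


def write_phased(
    pop: Population, path: str | Path, sample: CaseControlSample | None = None
) -> pd.DataFrame:
    """Write the phased-haplotype dialect: two nucleotide columns per SNP."""
    if pop.marker_haplotypes is None or pop.panel is None:
        raise ValidationError(
            "population has no phased haplotypes; use the genotypic dialect"
        )
    rows = _sample_rows(pop, sample)
    cols = _left_block(pop, rows)
    panel = pop.panel
    haps = pop.marker_haplotypes[rows]
    for j, mid in enumerate(panel.marker_ids):
        symbols = np.array(panel.alleles[j], dtype=object)
        cols[f"{mid}.1"] = symbols[haps[:, 0, j]]
        cols[f"{mid}.2"] = symbols[haps[:, 1, j]]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False)
    return df


def minor_allele_codes(panel: HaplotypePanel, locus: int) -> tuple[int, list[str]]:
    """Panel allele code (0/1) of the lower-frequency allele at ``locus``.

    Frequency ties are broken lexicographically: the alphabetically later
    symbol is treated as the minor allele.  Returns (code, notes).
    """
    f1 = float(panel.haplotypes[:, locus].mean())
    a0, a1 = panel.alleles[locus]
    if f1 < 0.5:
        return 1, []
    if f1 > 0.5:
        return 0, []
    minor = 1 if a1 > a0 else 0
    return minor, [
        f"marker {panel.marker_ids[locus]}: allele frequencies tied at 0.5; "
        f"minor allele taken as {panel.alleles[locus][minor]} (lexicographic)"
    ]


def write_genotypic(
    pop: Population, path: str | Path, sample: CaseControlSample | None = None
) -> pd.DataFrame:
    """Write the genotype-code dialect: one 1/2/3 column per SNP.

    DPL columns use the high-risk-allele coding carried by the population;
    other SNPs code the lower-frequency homozygote as 3.
    """
    rows = _sample_rows(pop, sample)
    cols = _left_block(pop, rows)
    if pop.panel is not None and pop.marker_haplotypes is not None:
        panel = pop.panel
        dpl_idx = {}
        for spec, g in ((pop.dpl_a, pop.genotype_a), (pop.dpl_b, pop.genotype_b)):
            if spec is not None:
                dpl_idx[panel.locus_index(spec.marker_id)] = g
        haps = pop.marker_haplotypes[rows]
        for j, mid in enumerate(panel.marker_ids):
            if j in dpl_idx:
                cols[mid] = dpl_idx[j][rows]
            else:
                minor, _ = minor_allele_codes(panel, j)
                cols[mid] = (haps[:, :, j] == minor).sum(axis=1) + 1
    else:
        id_a = pop.dpl_a.marker_id if pop.dpl_a is not None else "dpl_a"
        id_b = pop.dpl_b.marker_id if pop.dpl_b is not None else "dpl_b"
        cols[id_a] = pop.genotype_a[rows]
        cols[id_b] = pop.genotype_b[rows]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back either output dialect as a DataFrame (floats bit-exact)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_genotype_matrix(
    path: str | Path,
    dialect: str,
    dpl_a: LocusSpec,
    dpl_b: LocusSpec,
) -> Population:
    """Ingest an external genotype matrix (one row per individual).

    ``dialect`` is ``genotypic`` (one 1/2/3 column per SNP, DPL code 3 being
    the high-risk homozygote) or ``phased`` (two nucleotide columns per SNP
    named ``<id>.1``/``<id>.2``).  Only the two DPL columns are interpreted;
    the matrix is accepted as-is with no Hardy-Weinberg or LD enforcement.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if dialect == "genotypic":
        for spec in (dpl_a, dpl_b):
            if spec.marker_id not in df.columns:
                raise ValidationError(
                    f"DPL column {spec.marker_id!r} not found in genotype file"
                )
        ga = df[dpl_a.marker_id].to_numpy()
        gb = df[dpl_b.marker_id].to_numpy()
    elif dialect == "phased":
        def code(spec: LocusSpec) -> np.ndarray:
            c1, c2 = f"{spec.marker_id}.1", f"{spec.marker_id}.2"
            if c1 not in df.columns or c2 not in df.columns:
                raise ValidationError(
                    f"phased columns for DPL {spec.marker_id!r} not found"
                )
            copies = (df[c1] == spec.high_risk_allele).astype(int) + (
                df[c2] == spec.high_risk_allele
            ).astype(int)
            return (copies + 1).to_numpy()

        ga, gb = code(dpl_a), code(dpl_b)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    pop = Population(
        n=len(df),
        genotype_a=np.asarray(ga, dtype=np.int8),
        genotype_b=np.asarray(gb, dtype=np.int8),
    )
    pop.dpl_a, pop.dpl_b = dpl_a, dpl_b
    return pop


def write_snp_map(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the marker id / 1-based genomic position table."""
    pd.DataFrame(
        {"marker_id": panel.marker_ids, "position": panel.positions}
    ).to_csv(path, sep="\t", index=False)


def _fmt_matrix(name: str, m: np.ndarray) -> list[str]:
    m2 = np.atleast_2d(np.asarray(m, dtype=float))
    lines = [f"[{name}]"]
    for row in m2:
        lines.append("  " + "  ".join(f"{v: .10f}" for v in row))
    return lines


def write_log(artifacts, path: str | Path) -> None:
    """Write the extensive run report: every intermediate numeric table.

    Lines starting with '# ' carry volatile values (timings); everything else
    is a pure function of the configuration and seed.
    """
    a = artifacts
    lines: list[str] = ["== run configuration =="]
    for key, val in sorted(a.config_echo.items()):
        lines.append(f"{key}: {val}")
    lines.append("")
    lines.append("== genotype frequencies ==")
    lines += _fmt_matrix("P_ga", np.array(a.freqs_a.p))
    lines += _fmt_matrix("P_gb", np.array(a.freqs_b.p))
    lines.append("")
    lines.append("== marginal risks ==")
    lines += _fmt_matrix("TR_ga", a.marg.tr_a)
    lines += _fmt_matrix("TR_gb", a.marg.tr_b)
    lines.append("")
    lines.append("== penetrance matrices ==")
    lines += _fmt_matrix("TR_independent", a.tri.tr)
    lines += _fmt_matrix("Delta", a.delta.delta)
    lines += _fmt_matrix("TR_epistatic", a.tre.tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        lines += _fmt_matrix("TR_E/TR_I", np.where(a.tri.tr > 0, a.tre.tr / a.tri.tr, np.nan))
    lines.append("")
    lines.append("== multi-logistic coefficients ==")
    lines += _fmt_matrix("alpha", a.coeffs.alpha)
    lines += _fmt_matrix("beta", a.coeffs.beta)
    lines.append(f"beta_AB: {a.coeffs.beta_ab:.10f}")
    lines.append("")
    lines.append("== diagnostics ==")
    lines.append(f"prevalence target: {a.prevalence_report.target:.10f}")
    lines.append(f"prevalence implied: {a.prevalence_report.implied:.10f}")
    lines.append(f"prevalence residual: {a.prevalence_report.residual:.3e}")
    lines.append(f"prevalence check passed: {a.prevalence_report.passed}")
    for note in a.notes:
        lines.append(f"note: {note}")
    lines.append(f"seed: {a.config_echo.get('seed')}")
    for stage, seconds in a.timings.items():
        lines.append(f"# timing {stage}: {seconds:.3f}s")
    Path(path).write_text("\n".join(lines) + "\n")


def write_failure_log(message: str, path: str | Path) -> None:
    """Record why a run failed (the binding constraint) in the log file."""
    Path(path).write_text(
        "== run failed ==\n" + message + "\n"
    )
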
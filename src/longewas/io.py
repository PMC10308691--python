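"""Plain-text readers/writers for the pipeline's artifacts.

Formats: sample sheet CSV (one row per blood sample), beta matrix TSV (first
column cpg_id, then sample columns), CpG annotation TSV, truth TSV, residual
matrices as TSV with a ``# timepoint:`` header line, and the gene interval
TSV (1-based inclusive).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import MethylationStudy
from .simcohort import ReferencePanels, SimulatedStudy, subjects_frame


def write_study(out_dir: str | Path, sim: SimulatedStudy) -> dict[str, Path]:
    """Write samples.csv, beta.tsv, cpgs.tsv, truth.tsv and the panels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.csv",
        "beta": out / "beta.tsv",
        "annotation": out / "cpgs.tsv",
        "truth": out / "truth.tsv",
        "subjects": out / "subjects.csv",
        "panel_cord": out / "panel_cord.tsv",
        "panel_peripheral": out / "panel_peripheral.tsv",
    }
    sim.study.sample_metadata.to_csv(paths["samples"], index_label="sample_id")
    sim.study.beta.to_csv(paths["beta"], sep="\t", index_label="cpg_id")
    sim.study.cpg_annotation.to_csv(paths["annotation"], sep="\t", index_label="cpg_id")
    sim.truth.effects.to_csv(paths["truth"], sep="\t", index_label="cpg_id")
    subjects_frame(sim.subjects).to_csv(paths["subjects"])
    for name, panel, disc in [
        ("panel_cord", sim.panels.cord, sim.panels.cord_discriminating),
        ("panel_peripheral", sim.panels.peripheral, sim.panels.peripheral_discriminating),
    ]:
        with open(paths[name], "w") as fh:
            fh.write("# discriminating: " + ",".join(disc) + "\n")
            panel.to_csv(fh, sep="\t", index_label="cell_type")
    return paths


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def read_study(in_dir: str | Path) -> MethylationStudy:
    in_dir = Path(in_dir)
    return MethylationStudy(
        beta=read_beta_matrix(in_dir / "beta.tsv"),
        sample_metadata=read_sample_sheet(in_dir / "samples.csv"),
        cpg_annotation=read_annotation(in_dir / "cpgs.tsv"),
    )


def read_panel(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# discriminating:"):
            raise ValueError(f"{path} lacks the '# discriminating:' header line")
        disc = header.split(":", 1)[1].strip().split(",")
        panel = pd.read_csv(fh, sep="\t", index_col="cell_type")
    return panel, disc


def read_panels(in_dir: str | Path) -> ReferencePanels:
    in_dir = Path(in_dir)
    cord, cord_disc = read_panel(in_dir / "panel_cord.tsv")
    periph, periph_disc = read_panel(in_dir / "panel_peripheral.tsv")
    return ReferencePanels(
        cord=cord,
        peripheral=periph,
        cord_discriminating=cord_disc,
        peripheral_discriminating=periph_disc,
    )


def write_residuals(path: str | Path, residual: pd.DataFrame, timepoint: str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# timepoint: {timepoint}\n")
        residual.to_csv(fh, sep="\t", index_label="cpg_id")
    return path


def read_residuals(path: str | Path) -> tuple[pd.DataFrame, str]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# timepoint:"):
            raise ValueError(f"{path} lacks the '# timepoint:' header line")
        timepoint = header.split(":", 1)[1].strip()
        residual = pd.read_csv(fh, sep="\t", index_col="cpg_id")
    return residual, timepoint
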
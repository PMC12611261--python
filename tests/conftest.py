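import numpy as np
import pytest

from mmtpp.synth import SimConfig, simulate_experiment, write_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated experiment shared across read-only tests."""
    return simulate_experiment(SimConfig(n_proteins=120, seed=11))


@pytest.fixture(scope="session")
def tiny_dataset_dir(tiny_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_sim")
    write_dataset(tiny_dataset, out)
    return out


def write_pg_table(path, rows, sample_ids, intensity_prefix="LFQ intensity "):
    """Write a minimal proteinGroups-style table for fixtures.

    ``rows``: list of dicts with keys id, gene, reverse, contaminant,
    site_only, uniq, intensities (list aligned with sample_ids; None =
    missing).
    """
    header = [
        "Protein IDs", "Gene names", "Reverse", "Potential contaminant",
        "Only identified by site", "Unique peptides",
    ] + [intensity_prefix + s for s in sample_ids]
    lines = ["\t".join(header)]
    for r in rows:
        cells = [
            r["id"], r.get("gene", ""),
            "+" if r.get("reverse") else "",
            "+" if r.get("contaminant") else "",
            "+" if r.get("site_only") else "",
            str(r.get("uniq", "")),
        ]
        for v in r["intensities"]:
            cells.append("0" if v is None else f"{v!r}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
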
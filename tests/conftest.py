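import numpy as np
import pandas as pd
import pytest

from discoloc.io_formats import SummaryStats


def make_sumstats(rows, trait_name="trait", trait_type="quantitative"):
    """Build a SummaryStats from a list of dicts with canonical keys."""
    df = pd.DataFrame(rows)
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    if "P" not in df.columns:
        from scipy import stats
        df["LNP"] = np.log(2) + stats.norm.logsf(np.abs(df["Z"]))
        df["P"] = np.exp(df["LNP"])
    if "LNP" not in df.columns:
        with np.errstate(divide="ignore"):
            df["LNP"] = np.log(df["P"])
    return SummaryStats(df, trait_name=trait_name, trait_type=trait_type)


def variant_row(snp, pos, beta, se, ea="A", nea="G", eaf=0.3, chrom="1"):
    return {"SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "NEA": nea,
            "EAF": eaf, "BETA": beta, "SE": se}


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a canonical-column sumstats TSV and return its path."""
    def _write(rows, name="stats.tsv", columns=None):
        df = pd.DataFrame(rows)
        if columns:
            df = df.rename(columns=columns)
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path
    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
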
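"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates what the analysis needs from a seasonal river-basin
field campaign: per-sample EEMs that are trilinear mixtures of protein-like
and humic-like fluorophores (with optional Rayleigh/Raman scatter ridges and
heteroscedastic noise), a compositional OTU count table whose taxa are tied
to component scores with known signs, and a water-chemistry table driven by
the same latent scores.  Every dataset carries its ground truth so recovery
tests can score the pipeline against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eem import EEMSpectrum, raman_emission_center, write_eem
from .microbiome import OTUTable

PROTEIN_LIKE = "protein-like"
HUMIC_LIKE = "humic-like"

#: Dummy taxonomy backbone: six phyla that dominate temperate river surface waters plus
#: two fillers, each with a nominal class/order chain.
PHYLA = [
    "Proteobacteria", "Bacteroidota", "Actinobacteriota",
    "Verrucomicrobiota", "Firmicutes", "Cyanobacteria",
    "Acidobacteriota", "Chloroflexi",
]
_CLASSES = {
    "Proteobacteria": "Gammaproteobacteria",
    "Bacteroidota": "Bacteroidia",
    "Actinobacteriota": "Actinobacteria",
    "Verrucomicrobiota": "Verrucomicrobiae",
    "Firmicutes": "Bacilli",
    "Cyanobacteria": "Cyanobacteriia",
    "Acidobacteriota": "Vicinamibacteria",
    "Chloroflexi": "Anaerolineae",
}


@dataclass
class FluorophoreSpec:
    """One fluorophore: Gaussian excitation peak(s) and a Gaussian emission peak.

    ``excitation_peaks`` is a list of ``(center nm, width nm, relative height)``
    tuples; ``emission_peak`` is ``(center nm, width nm)``.
    """

    label: str
    excitation_peaks: list[tuple[float, float, float]]
    emission_peak: tuple[float, float]
    class_label: str = PROTEIN_LIKE

    def __post_init__(self) -> None:
        if not self.excitation_peaks:
            raise ValueError(f"{self.label}: needs at least one excitation peak")
        for c, w, h in self.excitation_peaks:
            if w <= 0:
                raise ValueError(f"{self.label}: excitation width must be > 0")
        if self.emission_peak[1] <= 0:
            raise ValueError(f"{self.label}: emission width must be > 0")
        min_ex = min(c for c, _, _ in self.excitation_peaks)
        if self.emission_peak[0] <= min_ex:
            raise ValueError(
                f"{self.label}: emission center must exceed smallest "
                "excitation center")

    def excitation_profile(self, ex: np.ndarray) -> np.ndarray:
        ex = np.asarray(ex, dtype=float)
        out = np.zeros_like(ex)
        for c, w, h in self.excitation_peaks:
            out += h * np.exp(-0.5 * ((ex - c) / w) ** 2)
        return out

    def emission_profile(self, em: np.ndarray) -> np.ndarray:
        em = np.asarray(em, dtype=float)
        c, w = self.emission_peak
        return np.exp(-0.5 * ((em - c) / w) ** 2)


def dry_season_fluorophores() -> list[FluorophoreSpec]:
    """The six dry-season components (tyrosine/tryptophan/humic-like peaks)."""
    return [
        FluorophoreSpec("D1", [(270, 12, 1.0)], (275, 18), PROTEIN_LIKE),
        FluorophoreSpec("D2", [(240, 12, 1.0), (290, 14, 0.7)], (395, 30),
                        HUMIC_LIKE),
        FluorophoreSpec("D3", [(245, 12, 1.0), (365, 18, 0.7)], (455, 35),
                        HUMIC_LIKE),
        FluorophoreSpec("D4", [(230, 10, 1.0)], (310, 20), PROTEIN_LIKE),
        FluorophoreSpec("D5", [(230, 10, 1.0), (280, 12, 0.8)], (335, 22),
                        PROTEIN_LIKE),
        FluorophoreSpec("D6", [(225, 10, 1.0)], (310, 20), PROTEIN_LIKE),
    ]


def wet_season_fluorophores() -> list[FluorophoreSpec]:
    """The six wet-season components."""
    return [
        FluorophoreSpec("W1", [(285, 12, 1.0), (330, 14, 0.8)], (410, 30),
                        HUMIC_LIKE),
        FluorophoreSpec("W2", [(280, 12, 1.0)], (330, 22), PROTEIN_LIKE),
        FluorophoreSpec("W3", [(245, 12, 1.0)], (405, 30), HUMIC_LIKE),
        FluorophoreSpec("W4", [(265, 12, 1.0), (365, 18, 0.7)], (460, 35),
                        HUMIC_LIKE),
        FluorophoreSpec("W5", [(270, 12, 1.0)], (305, 18), PROTEIN_LIKE),
        FluorophoreSpec("W6", [(220, 10, 1.0)], (335, 22), PROTEIN_LIKE),
    ]


def recovery_fluorophores() -> list[FluorophoreSpec]:
    """Three well-separated components used by the recovery fixtures."""
    return [
        FluorophoreSpec("D1", [(270, 12, 1.0)], (305, 18), PROTEIN_LIKE),
        FluorophoreSpec("D5", [(230, 10, 1.0), (280, 12, 0.8)], (345, 22),
                        PROTEIN_LIKE),
        FluorophoreSpec("D3", [(245, 12, 1.0), (365, 18, 0.7)], (455, 35),
                        HUMIC_LIKE),
    ]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``scores`` is the nonnegative sample x component concentration matrix;
    ``taxon_links``/``chemistry_links`` are ``(id, component label, sign,
    strength)`` tuples tying taxa or chemistry variables to components.
    """

    fluorophores: list[FluorophoreSpec]
    scores: np.ndarray
    taxon_links: list[tuple[str, str, int, float]] = field(default_factory=list)
    chemistry_links: list[tuple[str, str, int, float]] = field(
        default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("component scores must be nonnegative")
        labels = {f.label for f in self.fluorophores}
        for _, comp, _, _ in list(self.taxon_links) + list(self.chemistry_links):
            if comp not in labels:
                raise ValueError(f"link references unknown component {comp!r}")

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.fluorophores]

    def component_index(self, label: str) -> int:
        return self.labels.index(label)

    def zscores(self) -> np.ndarray:
        """Column-standardised component scores."""
        s = self.scores
        sd = s.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (s - s.mean(axis=0)) / sd

    def emission_loadings(self, em: np.ndarray) -> np.ndarray:
        return np.column_stack([f.emission_profile(em)
                                for f in self.fluorophores])

    def excitation_loadings(self, ex: np.ndarray) -> np.ndarray:
        return np.column_stack([f.excitation_profile(ex)
                                for f in self.fluorophores])

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "fluorophores": [asdict(f) for f in self.fluorophores],
            "scores": self.scores.tolist(),
            "taxon_links": [list(t) for t in self.taxon_links],
            "chemistry_links": [list(t) for t in self.chemistry_links],
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# EEM generation
# ---------------------------------------------------------------------------

def _scatter_ridges(ex: np.ndarray, em: np.ndarray, amplitude: float,
                    raman_shift_cm: float = 3400.0) -> np.ndarray:
    """Rayleigh (1st/2nd order) and Raman ridges on the (ex, em) grid.

    The Raman ridge sits at a fixed wavenumber shift below the excitation
    line, so at Ex 350 nm it falls inside the 371-428 nm emission window.
    """
    X = ex[:, None]
    Y = em[None, :]
    ridge = 4.0 * amplitude * np.exp(-0.5 * ((Y - X) / 5.0) ** 2)
    ridge += 1.0 * amplitude * np.exp(-0.5 * ((Y - 2 * X) / 5.0) ** 2)
    centers = np.array([raman_emission_center(x, raman_shift_cm)
                        for x in ex])[:, None]
    ridge += 0.5 * amplitude * np.exp(-0.5 * ((Y - centers) / 8.0) ** 2)
    return ridge


def generate_eem_dataset(
    n_samples: int,
    fluorophores: list[FluorophoreSpec] | None = None,
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
    noise_sd: float | None = None,
    scatter: bool = False,
    seed: int = 0,
    scores: np.ndarray | None = None,
    score_sdlog: float = 0.5,
) -> tuple[list[EEMSpectrum], SyntheticTruth]:
    """Generate a stack of synthetic EEMs plus their ground truth.

    Each EEM is the trilinear mixture
    ``sum_f score_if * ex_profile_f(ex) (x) em_profile_f(em)`` with
    optional scatter ridges and iid Gaussian noise of standard deviation
    ``noise_sd`` (default: 1% of the maximum noiseless signal).  Scores
    are drawn log-normal (meanlog 0, sdlog ``score_sdlog``) unless given.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if fluorophores is None:
        fluorophores = recovery_fluorophores()
    if ex_grid is None:
        ex_grid = np.arange(220.0, 451.0, 10.0)
    if em_grid is None:
        em_grid = np.arange(250.0, 551.0, 5.0)
    ex_grid = np.asarray(ex_grid, dtype=float)
    em_grid = np.asarray(em_grid, dtype=float)
    if np.any(np.diff(ex_grid) <= 0) or np.any(np.diff(em_grid) <= 0):
        raise ValueError("wavelength grids must be strictly increasing")
    for f in fluorophores:
        c = f.emission_peak[0]
        if not (em_grid[0] <= c <= em_grid[-1]):
            raise ValueError(
                f"emission grid does not cover component {f.label} "
                f"(peak {c} nm)")

    rng = np.random.default_rng(seed)
    F = len(fluorophores)
    if scores is None:
        scores = rng.lognormal(mean=0.0, sigma=score_sdlog,
                               size=(n_samples, F))
    scores = np.asarray(scores, dtype=float)

    C = np.column_stack([f.excitation_profile(ex_grid) for f in fluorophores])
    B = np.column_stack([f.emission_profile(em_grid) for f in fluorophores])
    clean = np.einsum("if,xf,mf->ixm", scores, C, B)
    peak = float(clean.max()) if clean.size else 1.0
    if noise_sd is None:
        noise_sd = 0.01 * peak

    eems = []
    for i in range(n_samples):
        grid = clean[i].copy()
        if scatter:
            grid += _scatter_ridges(ex_grid, em_grid, amplitude=peak)
        if noise_sd > 0:
            grid += rng.normal(0.0, noise_sd, size=grid.shape)
        eems.append(EEMSpectrum(ex=ex_grid.copy(), em=em_grid.copy(),
                                intensity=grid, sample_id=f"S{i + 1:02d}"))
    truth = SyntheticTruth(fluorophores=list(fluorophores), scores=scores,
                           seed=seed)
    return eems, truth


# ---------------------------------------------------------------------------
# OTU table generation
# ---------------------------------------------------------------------------

def default_taxon_links(truth: SyntheticTruth,
                        n_positive: int = 5, n_negative: int = 3,
                        strength: float = 2.0) -> list[tuple[str, str, int, float]]:
    """Plant positive and negative taxon-component links round-robin."""
    labels = truth.labels
    links = []
    for k in range(n_positive):
        links.append((f"OTU{k + 1:04d}", labels[k % len(labels)], 1, strength))
    for k in range(n_negative):
        links.append((f"OTU{n_positive + k + 1:04d}",
                      labels[k % len(labels)], -1, strength))
    return links


def generate_otu_table(truth: SyntheticTruth, n_taxa: int = 40,
                       depth: int = 20000, seed: int = 0,
                       base_sdlog: float = 1.0) -> OTUTable:
    """Multinomial OTU counts whose linked taxa track component scores.

    Latent per-taxon abundances are log-normal; a linked taxon's
    log-abundance is shifted by ``sign * strength * z`` where ``z`` is the
    standardised score of the linked component.  Counts are multinomial
    at the stated sequencing depth; column sums equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    linked = {t for t, _, _, _ in truth.taxon_links}
    if n_taxa < len(linked):
        raise ValueError(
            f"n_taxa={n_taxa} smaller than {len(linked)} linked taxa")
    rng = np.random.default_rng(seed)
    n_samples = truth.scores.shape[0]
    ids = [f"OTU{k + 1:04d}" for k in range(n_taxa)]
    for t in linked:
        if t not in ids:
            raise ValueError(f"linked taxon {t!r} outside generated id range")
    base = rng.normal(0.0, base_sdlog, size=n_taxa)
    z = truth.zscores()
    loga = np.tile(base[:, None], (1, n_samples))
    for taxon, comp, sign, strength in truth.taxon_links:
        loga[ids.index(taxon)] += sign * strength * z[:, truth.component_index(comp)]
    p = np.exp(loga)
    p /= p.sum(axis=0, keepdims=True)
    counts = np.column_stack([
        rng.multinomial(depth, p[:, j]) for j in range(n_samples)])
    lineages = {}
    for k, otu in enumerate(ids):
        phylum = PHYLA[k % len(PHYLA)]
        lineages[otu] = (
            f"d__Bacteria;p__{phylum};c__{_CLASSES[phylum]};"
            f"o__order{k % 4 + 1};f__family{k % 5 + 1};g__genus{k + 1}")
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    return OTUTable(counts=counts_df, lineages=pd.Series(lineages))


# ---------------------------------------------------------------------------
# Chemistry generation
# ---------------------------------------------------------------------------

CHEMISTRY_VARIABLES = ["COD_Cr", "COD_Mn", "TN", "TP", "NH3-N", "pH"]


def default_chemistry_links(truth: SyntheticTruth) -> list[tuple[str, str, int, float]]:
    """COD tracks the first protein-like component; TP the first humic-like."""
    protein = next((f.label for f in truth.fluorophores
                    if f.class_label == PROTEIN_LIKE), truth.labels[0])
    humic = next((f.label for f in truth.fluorophores
                  if f.class_label == HUMIC_LIKE), truth.labels[-1])
    return [
        ("COD_Cr", protein, 1, 0.5),
        ("COD_Mn", protein, 1, 0.4),
        ("TP", humic, 1, 0.4),
        ("TN", humic, 1, 0.3),
    ]


def generate_chemistry(truth: SyntheticTruth, seed: int = 0,
                       noise_sd: float = 0.05,
                       variables: list[str] | None = None) -> pd.DataFrame:
    """Positive water-chemistry variables driven by component scores.

    Each variable is ``exp(sum of sign*strength*z_component + noise)``
    (exponential link keeps concentrations positive); unlinked variables
    are constant up to noise.
    """
    if variables is None:
        variables = list(CHEMISTRY_VARIABLES)
    rng = np.random.default_rng(seed)
    n_samples = truth.scores.shape[0]
    z = truth.zscores()
    data = {}
    for var in variables:
        lin = np.zeros(n_samples)
        for name, comp, sign, strength in truth.chemistry_links:
            if name == var:
                lin += sign * strength * z[:, truth.component_index(comp)]
        if noise_sd > 0:
            lin += rng.normal(0.0, noise_sd, size=n_samples)
        data[var] = np.exp(lin)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    return pd.DataFrame(data, index=samples)


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(outdir, eems: list[EEMSpectrum], truth: SyntheticTruth,
                  otu: OTUTable | None = None,
                  chemistry: pd.DataFrame | None = None) -> dict[str, str]:
    """Write EEM CSVs, OTU/taxonomy TSVs, chemistry CSV and truth JSON.

    Returns a manifest mapping artifact names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    rows = []
    for eem in eems:
        path = outdir / f"eem_{eem.sample_id}.csv"
        write_eem(eem, path)
        rows.append({"sample_id": eem.sample_id, "eem_path": str(path)})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    manifest["manifest"] = str(outdir / "manifest.csv")
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    manifest["truth"] = str(outdir / "truth.json")
    if otu is not None:
        otu.counts.to_csv(outdir / "otu_counts.tsv", sep="\t",
                          index_label="OTU_ID")
        otu.lineages.rename("lineage").to_csv(
            outdir / "taxonomy.tsv", sep="\t", index_label="OTU_ID")
        manifest["otu"] = str(outdir / "otu_counts.tsv")
        manifest["taxonomy"] = str(outdir / "taxonomy.tsv")
    if chemistry is not None:
        chemistry.to_csv(outdir / "chemistry.csv", index_label="sample_id")
        manifest["chemistry"] = str(outdir / "chemistry.csv")
    return manifest
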
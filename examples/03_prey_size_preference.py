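"""Recover a known feeding kernel with the KDE-ratio preference analysis.

One sampling location, one predator species, ~10^4 prey draws from a
lognormal feeding kernel centred at -2.75 log10 g (about 1.8 mg prey).
The preference distribution — the normalised ratio of the realised (diet)
to environmental (zooplankton) kernel density estimates — should have its
mean at the kernel optimum.
"""

from sizesel import SimulationConfig, generate_dataset, selectivity_table
from sizesel.ppmr import stomach_summaries
from sizesel.preprocess import attach_station_covariates, drop_empty_stomachs

cfg = SimulationConfig(
    seed=7,
    n_stations=1,
    n_clusters=1,
    n_species=1,
    species_mass_medians=(0.5,),
    species_niche_sd=None,
    mass_sd=0.01,
    selectivity_intercept=-2.75,   # true optimal prey size (log10 g)
    selectivity_slope=0.0,
    selectivity_sd=0.3,            # kernel width
    beta_predator=0.0,
    n_fish_per_station=500,
    mean_prey_per_stomach=20.0,
    n_zoop_per_haul=300,
)
ds = generate_dataset(cfg)
stations = attach_station_covariates(ds.stations, ds.sst_daily)
predators = drop_empty_stomachs(ds.predators, ds.stomachs)
summaries = stomach_summaries(predators, ds.stomachs).merge(
    stations[["station", "sst", "lat", "lon"]], on="station"
)

table = selectivity_table(summaries, ds.stomachs, ds.zooplankton, stations)
print(table[["class_index", "n_predators", "n_prey", "mean_preferred_log10"]].to_string(index=False))
print()
best = table.sort_values("n_prey", ascending=False).iloc[0]
print(f"estimated mean preferred prey size: {best['mean_preferred_log10']:.3f} log10 g")
print("true kernel optimum:                -2.750 log10 g")
print()
print("Each row is one predator size class; with ample prey the estimate")
print("lands within a few hundredths of a log10 unit of the true optimum.")
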
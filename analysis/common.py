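"""Shared conditions for the analysis scripts.

One mid-sized study city drives scripts 01-05; the design studies (06-07)
sweep seeds and generator knobs around it.  Bulky pipeline artifacts live
under scratch/ (regenerated on demand, resumable); the small summary tables
every script writes live under results/.
"""

from pathlib import Path

from exposeg.pipeline import PipelineConfig
from exposeg.synthetic_city import CityConfig
from exposeg.trace_processing import HomeInferenceParams

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "pipeline_run"

STUDY_CITY = CityConfig(
    n_individuals=800,
    n_tracts=16,
    n_pois=80,
    n_hubs=6,
    n_days=10,
    venue_homophily=1.0,
    tract_ses_autocorrelation=0.6,
    hub_placement="embedded",
    duplicate_device_frac=0.02,
    seed=11,
)

STUDY_CONFIG = PipelineConfig(
    city=STUDY_CITY,
    home_params=HomeInferenceParams(min_pings=120),
    decompose_by=("component", "tie_bin", "time_window"),
    region_name="study-city",
)


def run_study_pipeline():
    """Run (or resume) the shared pipeline; returns the result bundle."""
    from exposeg.pipeline import run_pipeline
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return run_pipeline(STUDY_CONFIG, SCRATCH)
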
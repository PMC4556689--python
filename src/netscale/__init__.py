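"""netscale — mean-field correlations and scaling limits of recurrent
binary and leaky integrate-and-fire networks.

The package links the population-level effective connectivity of a
recurrent network to its pairwise averaged activity correlations, provides
the network-scaling transformations that preserve mean activities and
correlations together with their feasibility limits, reconstructs the
effective connectivity from cross-spectra, and ships reference simulators
that serve as the empirical oracle for every analytic claim.
"""

from importlib import resources

from .core import (
    CovarianceSet,
    DefectiveConnectivityError,
    Drive,
    EffectiveConnectivity,
    NetworkSpec,
    NeuronParams,
    PoleSet,
    SpecValidationError,
    WorkingPoint,
    load_network_spec,
    network_spec_from_dict,
    network_spec_to_dict,
    save_network_spec,
    working_point_equations,
)
from .binary import (
    BinaryCovarianceSolution,
    DegenerateSpectrumError,
    UnstableNetworkError,
    covariance_time_delayed,
    covariance_time_zero_delay,
    cross_spectrum_binary,
    effective_connectivity_binary,
    mean_activity,
    susceptibility,
    zero_lag_covariance,
)
from .lif import (
    covariance_time_lif,
    cross_spectrum_lif,
    effective_connectivity_lif,
    effective_weight,
    pole_spectrum,
    siegert_rate,
    solve_rates,
)
from .scaling import (
    ScalingResult,
    binary_generic_scaling_drive,
    binary_zero_lag_covariance,
    binary_zero_lag_scaling,
    min_kappa,
    scale_jk,
    symmetric_spiking_scaling,
)
from .simulate import (
    MeasuredCovariance,
    SimulationOutput,
    measure_covariances,
    simulate_binary,
    simulate_lif,
)
from .reconstruct import ReconstructionResult, detect_degeneracy, invert_cross_spectrum

__version__ = "0.1.0"


def example_spec(name: str) -> NetworkSpec:
    """Load one of the bundled example networks.

    Available: ``asymmetric_binary`` (two binary populations with
    population-specific connectivity), ``two_pop_lif`` (excitatory/
    inhibitory LIF network), ``symmetric_binary`` (self-sustaining binary
    network with population-independent connectivity).
    """
    ref = resources.files("netscale.data").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as path:
        return load_network_spec(path)
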
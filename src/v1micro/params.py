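"""Default model parameters.

Every number here is a model constant of the mouse V1 multi-column circuit:
neuron and synapse parameters of the leaky integrate-and-fire populations,
the layered-microcircuit connection-probability map the column inherits from
the Potjans–Diesmann lineage, external background-input fiber counts and
rates, and the coefficients of the four-population (Pyr, PV, SST, VIP)
firing-rate model of layer 2/3.

All currents are in pA, times in ms, voltages in mV, rates in Hz.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# LIF neuron parameters (identical for every cell in the network)
# ---------------------------------------------------------------------------

LIF_DEFAULTS = {
    "tau_m": 10.0,     # membrane time constant, ms
    "v_th": -50.0,     # spike threshold, mV
    "v_reset": -65.0,  # reset potential, mV
    "v_rest": -65.0,   # resting potential, mV (base-model lineage: = v_reset)
    "tau_ref": 3.0,    # absolute refractory period, ms
    "c_m": 250.0,      # membrane capacitance, pF
}

# ---------------------------------------------------------------------------
# Single-column population sizes (neurons per column)
# ---------------------------------------------------------------------------

NEURON_COUNTS = {
    "L23": {"E": 5171, "I": 1459},
    "L4": {"E": 5479, "I": 1370},
    "L5": {"E": 1213, "I": 266},
    "L6": {"E": 3599, "I": 737},
}

#: Fraction of superficial inhibitory cells per interneuron class.
#: VIP and SST are rounded (half-even); PV absorbs the remainder.
VIP_FRACTION = 0.24
SST_FRACTION = 0.30

N_THALAMIC_PER_COLUMN = 902

# ---------------------------------------------------------------------------
# Synaptic peak currents, w ± δw (pA).  Excitatory positive, inhibitory
# negative (Dale's law).  Pairs are keyed "SOURCE->TARGET".
# ---------------------------------------------------------------------------

PEAK_EXC_DEFAULT = (175.6, 17.6)
PEAK_INH_DEFAULT = (-702.4, 70.2)

PEAK_CURRENTS = {
    "PV->Pyr": (-466.7, 46.7),
    "PV->PV": (-638.1, 63.8),
    "PV->VIP": (-140.04, 14.0),
    "SST->Pyr": (-200.0, 20.0),
    "SST->PV": (-228.6, 22.9),
    "SST->VIP": (-525.8, 52.6),
    "VIP->Pyr": (-76.2, 7.62),
    "VIP->SST": (-66.7, 6.7),
    # the one interlaminar exception: L4 excitatory onto layer-2/3 pyramids
    "L4E->Pyr": (245.84, 24.6),
}

#: Background (external fiber) peak current, w ± δw (pA).
PEAK_BACKGROUND = (87.9, 8.8)

# ---------------------------------------------------------------------------
# Postsynaptic-current decay time constants (ms), per superficial pair.
# Connections not listed decay with the default 0.5 ms.
# ---------------------------------------------------------------------------

TAU_SYN_DEFAULT = 0.5

TAU_SYN = {
    "Pyr->Pyr": 2.0,
    "PV->Pyr": 6.0,
    "SST->Pyr": 7.5,
    "VIP->Pyr": 6.2,
    "Pyr->PV": 2.0,
    "PV->PV": 4.3,
    "SST->PV": 3.4,
    "Pyr->SST": 2.0,
    "VIP->SST": 10.4,
    "Pyr->VIP": 2.0,
    "PV->VIP": 4.3,
    "SST->VIP": 3.4,
}

# ---------------------------------------------------------------------------
# Synaptic conduction delays, d ± δd (ms)
# ---------------------------------------------------------------------------

DELAY_INTRA_EXC = (1.5, 0.75)
DELAY_INTRA_INH = (0.75, 0.375)
# intercolumnar conduction is 5x slower
DELAY_INTER_EXC = (7.5, 3.75)
DELAY_INTER_INH = (3.75, 1.88)

# ---------------------------------------------------------------------------
# Intercolumnar connections (superficial layers only).  Probabilities are
# fractions (printed as %).  Reach is the set of relative column offsets,
# applied with periodic boundary conditions.
# ---------------------------------------------------------------------------

INTERCOLUMNAR_RULES = {
    # source -> target: (probability, reach offsets)
    "Pyr->Pyr": (0.066, (-1, 1)),
    "Pyr->PV": (0.009, (-1, 1)),
    "PV->Pyr": (0.046, (-1, 1)),
    "Pyr->SST": (0.002, (-4, -3, -2, -1, 1, 2, 3, 4)),
}

# ---------------------------------------------------------------------------
# Weighting factors splitting the merged superficial inhibitory synapse
# budgets among the three interneuron classes.
# ---------------------------------------------------------------------------

#: Split of the I->E (inhibitory onto pyramidal) synapse budget.
WEIGHTS_I_TO_E = {"PV->Pyr": 1.0, "SST->Pyr": 1.0, "VIP->Pyr": 0.125}

#: Split of the I->I (inhibitory onto inhibitory) synapse budget.
WEIGHTS_I_TO_I = {
    "PV->PV": 1.0,
    "SST->PV": 0.857,
    "VIP->SST": 0.625,
    "SST->VIP": 1.0,
    "PV->VIP": 1.0,
}

# ---------------------------------------------------------------------------
# Layered-microcircuit connection probability map (Potjans–Diesmann 2014),
# the base model the column derives from.  p[target][source].  The merged
# L2/3 inhibitory entries apply identically to PV, SST and VIP for
# interlaminar connections; within layer 2/3 the E->E / E->I entries are the
# P_EE / P_EI of the base model and the I->E / I->I entries set the merged
# synapse budgets that are re-split by cell type.
# ---------------------------------------------------------------------------

PD_POPULATIONS = ("L23E", "L23I", "L4E", "L4I", "L5E", "L5I", "L6E", "L6I")

PD_CONN_PROB = {
    "L23E": {"L23E": 0.1009, "L23I": 0.1689, "L4E": 0.0437, "L4I": 0.0818,
             "L5E": 0.0323, "L5I": 0.0, "L6E": 0.0076, "L6I": 0.0},
    "L23I": {"L23E": 0.1346, "L23I": 0.1371, "L4E": 0.0316, "L4I": 0.0515,
             "L5E": 0.0755, "L5I": 0.0, "L6E": 0.0042, "L6I": 0.0},
    "L4E": {"L23E": 0.0077, "L23I": 0.0059, "L4E": 0.0497, "L4I": 0.1350,
            "L5E": 0.0067, "L5I": 0.0003, "L6E": 0.0453, "L6I": 0.0},
    "L4I": {"L23E": 0.0691, "L23I": 0.0029, "L4E": 0.0794, "L4I": 0.1597,
            "L5E": 0.0033, "L5I": 0.0, "L6E": 0.1057, "L6I": 0.0},
    "L5E": {"L23E": 0.1004, "L23I": 0.0622, "L4E": 0.0505, "L4I": 0.0057,
            "L5E": 0.0831, "L5I": 0.3726, "L6E": 0.0204, "L6I": 0.0},
    "L5I": {"L23E": 0.0548, "L23I": 0.0269, "L4E": 0.0257, "L4I": 0.0022,
            "L5E": 0.0600, "L5I": 0.3158, "L6E": 0.0086, "L6I": 0.0},
    "L6E": {"L23E": 0.0156, "L23I": 0.0066, "L4E": 0.0211, "L4I": 0.0166,
            "L5E": 0.0572, "L5I": 0.0197, "L6E": 0.0396, "L6I": 0.2252},
    "L6I": {"L23E": 0.0364, "L23I": 0.0010, "L4E": 0.0034, "L4I": 0.0005,
            "L5E": 0.0277, "L5I": 0.0080, "L6E": 0.0658, "L6I": 0.1443},
}

#: Thalamic connection probabilities onto layer 4 and layer 6.
PD_THALAMIC_PROB = {"L4E": 0.0983, "L4I": 0.0619, "L6E": 0.0512, "L6I": 0.0196}

# ---------------------------------------------------------------------------
# External background inputs: fiber counts per population and the rate (Hz)
# carried by each independent Poisson fiber.
# ---------------------------------------------------------------------------

BACKGROUND_FIBERS = {
    "L23E": 1600, "L23I": 1500,
    "L4E": 2100, "L4I": 1900,
    "L5E": 2000, "L5I": 1900,
    "L6E": 2900, "L6I": 2100,
}

BACKGROUND_RATES = {
    "L23_Pyr": 8.0, "L23_PV": 10.0, "L23_SST": 2.0, "L23_VIP": 8.0,
    "L4_E": 8.0, "L4_I": 8.0,
    "L5_E": 8.0, "L5_I": 8.0,
    "L6_E": 8.0, "L6_I": 8.0,
}

# ---------------------------------------------------------------------------
# Four-population firing-rate model of layer 2/3 (Wilson–Cowan type, square
# root gain fitted to the LIF F-I curve: g(u) = 5.33 * sqrt(u - theta) for
# u > theta).  Weights S_xy are in pA per Hz; applied currents I_x in pA.
# ---------------------------------------------------------------------------

RATE_MODEL_DEFAULTS = {
    "S_ee": 1.98, "S_ep": 5.68, "S_es": 3.05, "S_ev": 0.12,
    "S_pe": 0.55, "S_pp": 2.28, "S_ps": 0.55,
    "S_se": 0.55, "S_sv": 0.36,
    "S_ve": 0.55, "S_vp": 0.50, "S_vs": 1.48,
    "I_e": 366.0, "I_p": 362.0, "I_s": 361.0, "I_v": 370.0,
    "theta": 360.0,
    "tau_m": 10.0,
    "gain_coeff_e": 5.33, "gain_coeff_p": 5.33,
    "gain_coeff_s": 5.33, "gain_coeff_v": 5.33,
}

#: Default simulation resolution (ms).
DT_DEFAULT = 0.1
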
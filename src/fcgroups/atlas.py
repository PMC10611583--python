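"""Canonical resting-state networks and the five reference group templates.

The node universe is a configurable number of ROIs partitioned into 16
canonical networks: six prefrontal networks (four "top-down" self-regulatory
ones — default mode, cingulo-opercular, fronto-parietal, dorsal attention —
and two "bottom-up" reactive ones — ventral attention, salience) plus ten
automatically co-activated sensory, motor and subcortical modules.

Each reference group template records, per network, whether members'
connectivity is elevated (+1) or reduced (-1) relative to healthy controls,
with a ``bold`` flag marking the strongest deviations, together with the
temperament/character profile and symptom profile that co-vary with
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical network codes, in the conventional presentation order.
NETWORKS: tuple[str, ...] = (
    "DMN",   # Default Mode
    "CON",   # Cingulo-Opercular
    "FPN",   # Fronto-Parietal
    "DAN",   # Dorsal Attention
    "VAN",   # Ventral Attention
    "SAL",   # Salience
    "VIS",   # Visual
    "AUD",   # Auditory
    "THA",   # Thalamus
    "STR",   # Striatum
    "CTX",   # Context / memory retrieval
    "PER",   # Perception (cerebellar-perceptual)
    "SMH",   # Sensorimotor hand
    "SMM",   # Sensorimotor mouth
    "AMY",   # Amygdala
    "ENT",   # Entorhinal
)

NETWORK_INDEX = {name: i for i, name in enumerate(NETWORKS)}

#: The seven Temperament and Character Inventory dimensions.
TCI_DIMENSIONS: tuple[str, ...] = ("NS", "HA", "RD", "PS", "SD", "CO", "ST")

#: SANS/SAPS composite symptom scores.
CLINICAL_COMPOSITES: tuple[str, ...] = ("positive_sx", "disorganization_sx", "negative_sx")


@dataclass(frozen=True)
class GroupTemplate:
    """Connectivity / personality / clinical signature of one patient group."""

    name: str
    #: network -> (sign, bold); sign in {+1, -1}; unlisted networks are null.
    network_signs: dict[str, tuple[int, bool]]
    #: TCI dimension -> +1 (high) or -1 (low); unlisted dimensions neutral.
    tci_profile: dict[str, int]
    #: symptom composite -> +1 (elevated); unlisted composites neutral.
    clinical_profile: dict[str, int]
    n_sz: int
    n_bp: int

    @property
    def size(self) -> int:
        return self.n_sz + self.n_bp


#: The five reference patient-group templates. Bold flags mark the most
#: pronounced deviations from healthy-control connectivity.
GROUP_TEMPLATES: tuple[GroupTemplate, ...] = (
    GroupTemplate(
        name="Avoidant-Anhedonic",
        network_signs={
            "DMN": (+1, True), "CON": (+1, False), "FPN": (+1, True),
            "DAN": (+1, False), "VAN": (+1, True), "VIS": (+1, False),
        },
        tci_profile={"HA": +1, "SD": -1},
        clinical_profile={"negative_sx": +1},
        n_sz=5, n_bp=6,
    ),
    GroupTemplate(
        name="Sensitive-Disorganized",
        network_signs={
            "DMN": (+1, True), "CON": (+1, True), "FPN": (+1, True),
            "DAN": (+1, True), "VAN": (+1, True), "SAL": (+1, False),
            "VIS": (+1, True), "AUD": (+1, False), "STR": (+1, False),
            "PER": (+1, False), "SMH": (+1, True), "SMM": (+1, True),
        },
        tci_profile={"HA": +1, "NS": +1, "SD": -1, "CO": -1, "ST": +1},
        clinical_profile={"negative_sx": +1, "disorganization_sx": +1},
        n_sz=10, n_bp=17,
    ),
    GroupTemplate(
        name="Asocial-Blocked",
        network_signs={
            "DMN": (-1, True), "CON": (+1, True), "FPN": (+1, True),
            "DAN": (+1, True), "VAN": (-1, True), "VIS": (-1, True),
            "AUD": (+1, True), "THA": (+1, False), "STR": (+1, False),
            "CTX": (+1, True), "PER": (+1, False), "SMH": (+1, True),
            "SMM": (-1, False),
        },
        tci_profile={"NS": +1, "CO": -1, "ST": +1},
        clinical_profile={"negative_sx": +1, "positive_sx": +1},
        n_sz=4, n_bp=6,
    ),
    GroupTemplate(
        name="Fragile-Avolitional",
        network_signs={
            "DMN": (-1, False), "CON": (-1, True), "FPN": (+1, False),
            "DAN": (+1, False), "VAN": (-1, False), "VIS": (-1, True),
            "AUD": (-1, True), "THA": (-1, False), "STR": (-1, True),
            "PER": (+1, False), "SMH": (-1, True), "SMM": (-1, True),
        },
        tci_profile={"PS": -1, "HA": +1, "NS": +1, "SD": -1},
        clinical_profile={"negative_sx": +1, "positive_sx": +1},
        n_sz=17, n_bp=18,
    ),
    GroupTemplate(
        name="Explosive-Inattentive",
        network_signs={
            "DMN": (-1, True), "CON": (-1, True), "FPN": (+1, False),
            "DAN": (-1, True), "VAN": (-1, False), "VIS": (-1, True),
            "CTX": (-1, False), "PER": (-1, False), "SMH": (-1, True),
            "SMM": (+1, False),
        },
        tci_profile={"RD": -1, "HA": +1, "NS": +1, "SD": -1, "CO": -1, "ST": +1},
        clinical_profile={"disorganization_sx": +1},
        n_sz=8, n_bp=8,
    ),
)


def block_sign(template: GroupTemplate, net_a: str, net_b: str) -> tuple[int, bool]:
    """Sign and bold flag of the (net_a, net_b) connectivity block for a group.

    Per-network directions are lifted to network-pair blocks: a within-network
    block takes the network's own sign; a between-network block deviates only
    when both networks deviate in the same direction, and is bold only when
    both are bold.
    """
    sa, ba = template.network_signs.get(net_a, (0, False))
    sb, bb = template.network_signs.get(net_b, (0, False))
    if net_a == net_b:
        return sa, ba
    if sa != 0 and sa == sb:
        return sa, ba and bb
    return 0, False


def default_node_network_map(n_nodes: int) -> list[str]:
    """Assign ``n_nodes`` ROIs to the 16 networks as evenly as possible.

    Nodes are laid out network-contiguously (all DMN nodes first, etc.);
    remainders go to the earliest networks. Requires at least one node per
    network.
    """
    if n_nodes < len(NETWORKS):
        raise ValueError(
            f"need at least {len(NETWORKS)} nodes (one per network), got {n_nodes}"
        )
    base, extra = divmod(n_nodes, len(NETWORKS))
    out: list[str] = []
    for i, net in enumerate(NETWORKS):
        out.extend([net] * (base + (1 if i < extra else 0)))
    return out
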
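abbreviation	region	tier
Fpole	Frontal Pole	cortical
IC	Insular Cortex	cortical
SFG	Superior Frontal Gyrus	cortical
MFG	Middle Frontal Gyrus	cortical
IFGtriang	Inferior Frontal Gyrus, pars triangularis	cortical
IFGoper	Inferior Frontal Gyrus, pars opercularis	cortical
PreC	Precentral Gyrus	cortical
Tpole	Temporal Pole	cortical
STGant	Anterior Superior Temporal Gyrus	cortical
STGpost	Posterior Superior Temporal Gyrus	cortical
MTGant	Anterior Middle Temporal Gyrus	cortical
MTGpost	Posterior Middle Temporal Gyrus	cortical
MTGto	Temporoccipital part of Middle Temporal Gyrus	cortical
ITGant	Anterior Inferior Temporal Gyrus	cortical
ITGpost	Posterior Inferior Temporal Gyrus	cortical
ITGto	Temporoccipital part of Inferior Temporal Gyrus	cortical
PostC	Postcentral Gyrus	cortical
SPL	Superior Parietal Lobule	cortical
SMGant	Anterior Supramarginal Gyrus	cortical
SMGpost	Posterior Supramarginal Gyrus	cortical
ANG	Angular Gyrus	cortical
LOCsup	Superior Lateral Occipital Cortex	cortical
LOCinf	Inferior Lateral Occipital Cortex	cortical
IntraCAL	Intracalcarine Cortex	cortical
FMC	Frontal Medial Cortex	cortical
SMA	Juxtapositional Lobule	cortical
Subcallosal	Subcallosal Cortex	cortical
ParaCG	Paracingulate Cortex	cortical
ACG	Anterior Cingulate Gyrus	cortical
PCG	Posterior Cingulate Gyrus	cortical
PCUN	Precuneus Cortex	cortical
CUN	Cuneal Cortex	cortical
FOrb	Frontal Orbital Cortex	cortical
PHIPant	Anterior Parahippocampus	cortical
PHIPpost	Posterior Parahippocampus	cortical
LIN	Lingual Gyrus	cortical
TFUSant	Anterior Division of Temporal Fusiform Cortex	cortical
TFUSpost	Posterior Division of Temporal Fusiform Cortex	cortical
TOFus	Temporal Occipital Fusiform Cortex	cortical
OFus	Occipital Fusiform Cortex	cortical
FOper	Frontal Operculum	cortical
COper	Central Operculum	cortical
POper	Parietal Operculum	cortical
PPolare	Planum Polare	cortical
HES	Heschl's Gyrus	cortical
PTemporale	Planum Temporale	cortical
SupraCAL	Supracalcarine Cortex	cortical
Opole	Occipital Pole	cortical
THA	Thalamus	subcortical
PUT	Putamen	subcortical
CAU	Caudate	subcortical
PAL	Pallidum	subcortical
HIP	Hippocampus	subcortical
AMYG	Amygdala	subcortical
NAC	Nucleus Accumbens	subcortical
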
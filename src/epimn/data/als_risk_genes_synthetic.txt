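# Synthetic placeholder ALS risk-gene list (81 entries).
# These are generated stand-in identifiers for tests and demos,
# not the curated risk-gene panel; supply your own list via
# epimn.genome.read_gene_set for real analyses.
RISK001
RISK002
RISK003
RISK004
RISK005
RISK006
RISK007
RISK008
RISK009
RISK010
RISK011
RISK012
RISK013
RISK014
RISK015
RISK016
RISK017
RISK018
RISK019
RISK020
RISK021
RISK022
RISK023
RISK024
RISK025
RISK026
RISK027
RISK028
RISK029
RISK030
RISK031
RISK032
RISK033
RISK034
RISK035
RISK036
RISK037
RISK038
RISK039
RISK040
RISK041
RISK042
RISK043
RISK044
RISK045
RISK046
RISK047
RISK048
RISK049
RISK050
RISK051
RISK052
RISK053
RISK054
RISK055
RISK056
RISK057
RISK058
RISK059
RISK060
RISK061
RISK062
RISK063
RISK064
RISK065
RISK066
RISK067
RISK068
RISK069
RISK070
RISK071
RISK072
RISK073
RISK074
RISK075
RISK076
RISK077
RISK078
RISK079
RISK080
RISK081
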
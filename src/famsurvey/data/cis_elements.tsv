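element_name	pattern	category	subcategory
TATA-box	TATAAAT	transcription	core promoter
CAAT-box	CCAATT	transcription	common enhancer
ABRE	TACGTGTC	hormone	ABA-responsive
TGACG-motif	TGACGTCA	hormone	MeJA-responsive
CGTCA-motif	CGTCATGA	hormone	MeJA-responsive
TCA-element	CCATCTTTTT	hormone	SA-responsive
TGA-element	AACGACAA	hormone	IAA-responsive
AuxRR-core	GGTCCAT	hormone	IAA-responsive
GARE-motif	TCTGTTG	hormone	GA-responsive
P-box	CCTTTTG	hormone	GA-responsive
ERE	ATTTTAAA	hormone	ethylene-responsive
ARE	TGGTTT	stress	anaerobic induction
LTR	CCGAAA	stress	low-temperature-responsive
MBS	TAACTG	stress	drought/MYB binding
TC-rich	ATTTTCTTCA	stress	defense and stress
WUN-motif	AAATTTCCT	stress	wound-responsive
W-box	TTGACC	stress	pathogen/WRKY binding
DRE-core	GCCGAC	stress	dehydration-responsive
O2-site	GATGACATGG	development	zein metabolism regulation
GCN4-motif	TGAGTCA	development	endosperm expression
CAT-box	GCCACT	development	meristem expression
circadian	CAAAGATATC	development	circadian control
RY-element	CATGCATG	development	seed-specific regulation
HD-Zip1	CAATAATTG	development	palisade mesophyll cell
MSA-like	TCCAACGG	cell_cycle	cell cycle regulation
E2F-site	TTTCCCGC	cell_cycle	cell cycle regulation
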
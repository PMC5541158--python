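canonical_trait	synonym	polarity
nitrate_reduction	nitrate reductase activity found	positive
nitrate_reduction	denitrification activity	positive
nitrate_reduction	nitrate reductase present	positive
nitrate_reduction	positive reduction of nitrate	positive
nitrate_reduction	positive nitrate reduction	positive
nitrate_reduction	positive for nitrate reductase	positive
nitrate_reduction	positive for nitrate reduction	positive
nitrate_reduction	capable of nitrate reduction	positive
nitrate_reduction	nitrate reducer	positive
nitrate_reduction	nitrate not reduced	negative
nitrate_reduction	negative for nitrate reduction	negative
nitrate_reduction	does not reduce nitrate	negative
urease	urease positive	positive
urease	urease activity found	positive
urease	urease negative	negative
oxidase	oxidase positive	positive
oxidase	oxidase-positive	positive
oxidase	oxidase negative	negative
catalase	catalase positive	positive
catalase	catalase-positive	positive
catalase	catalase negative	negative
nitrogen_fixation	fixes nitrogen	positive
nitrogen_fixation	nitrogen-fixing	positive
nitrogen_fixation	diazotroph	positive
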
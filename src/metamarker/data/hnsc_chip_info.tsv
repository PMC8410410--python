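Name	country	year
GSE11163	USA	2008
GSE22587	China	2013
GSE28100	USA	2012
GSE31277	Brazil	2014
GSE32906	China	2012
GSE32960	China	2012
GSE34496	USA	2013
GSE36682	China	2012
GSE41268	China	2012
GSE43329	China	2013
GSE45238	China	2015
GSE46172	USA	2014
GSE62819	China	2014
GSE69002	USA	2016
GSE73171	China	2016
GSE82064	Switzerland	2017
GSE98463	Spain	2017
GSE103931	USA	2017
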
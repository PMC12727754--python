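We aim to evaluate the creativity of solutions in the Fusion Innovation Test (FIT) based on specific criteria. In each question of FIT, people will be presented with 2 elements and 1 goal, and they are required to come up with creative solutions that combine the 2 provided elements to achieve the given goal. In a solution, the 2 given elements must be used, but they were allowed to add additional elements into their solutions whenever needed.

Please rate these solutions, given below, in terms of the Feasibility of the combination of 2 elements in solutions, which is defined as follows:
Rate the feasibility of the combination of 2 elements in a solution on a scale of 1-100, with 1 being not feasible at all and 100 being extremely feasible. Consider how practical or doable in real-life the way two elements are combined in the solution, while disregarding the novelty of the combination of 2 elements and goal attainment level in the solution. Make sure to give a rating to every solution, disregarding the quality of the sentence.
Proceed as follows in your evaluation:
Write 3 (three) lines for each solution in the list below. On the first line, write the solution number and briefly describe the solution in your own words. On the second line, consider other feasible ways to combine the two elements, including those listed, and compare the solution to these in terms of its Feasibility of the combination of 2 elements. Finally, on the third line, provide your numeric rating as a json object of the form {"feasibility":x}. Evaluate each solution in the order provided, leaving one empty line between evaluations. Do evaluate each of the 20 solutions below individually and make sure to give a rating to every solution, even if there are repetitions.

FIT question
Elements:
(1) Digital camera
(2) Coloring book
Goal: Foster personal creativity and expression

Solutions:
(1) Photograph everyday scenes with the digital camera and print them as line-art pages for the coloring book.
(2) Use the coloring book as a storyboard and re-shoot each colored page with the digital camera into a stop-motion film.
(3) Scan finished coloring-book pages with the digital camera and blend them into photo collages.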